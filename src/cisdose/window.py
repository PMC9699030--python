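"""Therapeutic-window identification from an exposure-outcome cohort.

The window is the closed exposure interval [lower, upper] maximizing the
concordance objective: the number of patients who either lie inside the
window with a positive composite outcome or outside it with a negative one.
Two searchers are provided — an exhaustive grid search, which is exact up
to its step and serves as the reference oracle, and a tree-structured
Parzen estimator (TPE) working on the continuous (lower, width)
parameterization, as used in the original analysis.  Contingency tables in
the style of a within/outside-range summary complete the module.

The TPE here is a minimal adaptive-Parzen sampler in the lineage of the
original hyperopt estimator.  After a batch of startup trials (which
always include the trivial all-inside and all-outside windows, so the
search can never do worse than either), completed trials are ranked and
the best ceil(0.25 * sqrt(n)) of them (capped at 25) form the "good" set;
the rest form the "bad" set.  Per coordinate, an equal-weight Gaussian
mixture with neighbour-spacing bandwidths plus one uniform prior
component models each set, candidates are sampled from the good mixture,
and the candidate maximizing the density ratio l(x)/g(x) becomes the next
trial.  Every fourth trial is drawn from the uniform prior instead
(sustained exploration — the concordance objective is piecewise constant
and traps purely exploitative samplers on plateaus), and the trial budget
is split over two independent runs whose best trial is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import proportions_from_counts

__all__ = [
    "TherapeuticWindow",
    "ContingencySummary",
    "InvalidWindowError",
    "concordance",
    "grid_search",
    "tpe_search",
    "contingency",
]

TPE_GAMMA = 0.25          # good-set fraction, applied to sqrt(n) as in hyperopt
TPE_GOOD_CAP = 25         # never keep more than this many good trials
TPE_N_STARTUP = 20        # random trials before the Parzen model kicks in
TPE_N_CANDIDATES = 24     # candidates scored per TPE iteration
TPE_EXPLORE_EVERY = 4     # every k-th trial is drawn from the uniform prior
TPE_RESTARTS = 2          # independent runs sharing the trial budget
MIN_TRIALS = 10


class InvalidWindowError(ValueError):
    """lower >= upper, or too few trials / exposures to search."""


@dataclass(frozen=True)
class TherapeuticWindow:
    lower: float
    upper: float
    objective: int          #: concordant-patient count
    n_inside: int
    n_outside: int

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise InvalidWindowError(
                f"need lower < upper, got [{self.lower}, {self.upper}]"
            )

    def contains(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x >= self.lower) & (x <= self.upper)

    def as_dict(self) -> dict:
        return {"lower": self.lower, "upper": self.upper,
                "objective": self.objective, "n_inside": self.n_inside,
                "n_outside": self.n_outside}


@dataclass(frozen=True)
class ContingencySummary:
    """Per-outcome 2x2 counts (yes/no x inside/outside the window)."""

    n_inside: int
    n_outside: int
    tables: dict  # outcome name -> dict(yes_inside, no_inside, yes_outside, no_outside)

    def percentages(self) -> dict:
        out = {}
        for name, t in self.tables.items():
            out[name] = {
                "yes_inside_pct": proportions_from_counts(t["yes_inside"], self.n_inside),
                "no_inside_pct": proportions_from_counts(t["no_inside"], self.n_inside),
                "yes_outside_pct": proportions_from_counts(t["yes_outside"], self.n_outside),
                "no_outside_pct": proportions_from_counts(t["no_outside"], self.n_outside),
            }
        return out


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def concordance(lower: float, upper: float, exposures, benefit) -> int:
    """Count patients concordant with the window [lower, upper] (closed).

    A patient is concordant when inside with a positive outcome or outside
    with a negative one.
    """
    if not lower < upper:
        raise InvalidWindowError(f"need lower < upper, got [{lower}, {upper}]")
    x = np.asarray(exposures, dtype=float)
    b = np.asarray(benefit, dtype=bool)
    if x.shape != b.shape:
        raise ValueError("exposures and benefit must have equal length")
    inside = (x >= lower) & (x <= upper)
    return int(np.sum(inside == b))


# ---------------------------------------------------------------------------
# exhaustive grid oracle
# ---------------------------------------------------------------------------

def grid_search(exposures, benefit, step: float = 0.1) -> TherapeuticWindow:
    """Exhaustive concordance maximization over a regular (lower, upper) grid.

    The grid spans [min(x) - step, max(x) + step].  Ties are broken in
    favour of the widest window, then the lowest lower bound, which yields
    the most permissive dosing target among equal-objective windows.
    """
    x = np.asarray(exposures, dtype=float)
    b = np.asarray(benefit, dtype=bool)
    if np.unique(x).size < 2:
        raise InvalidWindowError("need at least 2 distinct exposure values")
    lo0, hi0 = x.min() - step, x.max() + step
    grid = np.arange(lo0, hi0 + step / 2.0, step)
    m = grid.size

    # inside[i, j, k]: grid[i] <= x[k] <= grid[j]
    ge = x[None, :] >= grid[:, None]          # (m, n)
    le = x[None, :] <= grid[:, None]          # (m, n)
    best = (-1, -np.inf, np.inf)              # (objective, width, -lower) ordering
    best_ij = None
    for i in range(m - 1):
        # scores for all uppers j > i at once
        inside = ge[i][None, :] & le[i + 1:]          # (m-i-1, n)
        obj = np.sum(inside == b[None, :], axis=1)    # (m-i-1,)
        j_rel = int(np.argmax(obj + np.arange(obj.size) * 1e-9))  # widest among ties
        cand = (int(obj[j_rel]), grid[i + 1 + j_rel] - grid[i], -grid[i])
        if cand > best:
            best = cand
            best_ij = (i, i + 1 + j_rel)
    i, j = best_ij
    lower, upper = float(grid[i]), float(grid[j])
    n_inside = int(np.sum((x >= lower) & (x <= upper)))
    return TherapeuticWindow(lower=lower, upper=upper, objective=best[0],
                             n_inside=n_inside, n_outside=x.size - n_inside)


# ---------------------------------------------------------------------------
# tree-structured Parzen estimator
# ---------------------------------------------------------------------------

def _adaptive_bandwidths(vals: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Per-kernel bandwidths from neighbour spacing (adaptive Parzen)."""
    order = np.argsort(vals)
    s = vals[order]
    ext = np.concatenate([[lo], s, [hi]])
    widths = np.maximum(ext[1:-1] - ext[:-2], ext[2:] - ext[1:-1])
    bw = np.empty_like(vals)
    bw[order] = widths
    span = hi - lo
    return np.clip(bw, 0.01 * span, span)


def _parzen_logpdf(xq: np.ndarray, centers: np.ndarray, bw: np.ndarray,
                   lo: float, hi: float) -> np.ndarray:
    """Log density of the kernel mixture plus one uniform prior component."""
    z = (xq[:, None] - centers[None, :]) / bw[None, :]
    log_k = -0.5 * z * z - np.log(bw[None, :] * np.sqrt(2.0 * np.pi))
    log_kern = np.logaddexp.reduce(log_k, axis=1)
    log_unif = np.full(len(xq), -np.log(hi - lo))
    return np.logaddexp(log_kern, log_unif) - np.log(len(centers) + 1)


def _tpe_run(x: np.ndarray, b: np.ndarray, n_trials: int,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, float]:
    """One TPE run; returns trial parameters, scores and the search span."""
    margin = 0.1
    lo0, hi0 = x.min() - margin, x.max() + margin
    span = hi0 - lo0
    w_min = 1e-3 * span
    bounds = [(lo0, hi0 - w_min), (w_min, span)]  # (lower, width)

    params = np.empty((n_trials, 2))
    scores = np.empty(n_trials, dtype=int)

    def evaluate(i: int, lower: float, width: float) -> None:
        lower = float(np.clip(lower, lo0, hi0 - w_min))
        width = float(np.clip(width, w_min, hi0 - lower))
        params[i] = (lower, width)
        scores[i] = concordance(lower, lower + width, x, b)

    # trivial windows first: all-inside and all-outside (below min(x))
    evaluate(0, lo0, span)
    evaluate(1, lo0, (x.min() - lo0) / 2.0)
    for i in range(2, min(TPE_N_STARTUP, n_trials)):
        evaluate(i, rng.uniform(*bounds[0]), rng.uniform(*bounds[1]))

    for i in range(min(TPE_N_STARTUP, n_trials), n_trials):
        if i % TPE_EXPLORE_EVERY == 0:  # periodic draw from the prior
            evaluate(i, rng.uniform(*bounds[0]), rng.uniform(*bounds[1]))
            continue
        n_good = max(2, min(TPE_GOOD_CAP, int(np.ceil(TPE_GAMMA * np.sqrt(i)))))
        order = np.argsort(-scores[:i], kind="stable")
        good, bad = params[order[:n_good]], params[order[n_good:]]
        cand = np.empty((TPE_N_CANDIDATES, 2))
        ratio = np.zeros(TPE_N_CANDIDATES)
        for dim, (lo_d, hi_d) in enumerate(bounds):
            bw_g = _adaptive_bandwidths(good[:, dim], lo_d, hi_d)
            bw_b = _adaptive_bandwidths(bad[:, dim], lo_d, hi_d)
            # sample candidates from the good mixture (prior = extra component)
            comp = rng.integers(0, len(good) + 1, TPE_N_CANDIDATES)
            from_prior = rng.uniform(lo_d, hi_d, TPE_N_CANDIDATES)
            idx = comp % len(good)
            from_kern = np.clip(
                good[idx, dim] + rng.normal(0.0, 1.0, TPE_N_CANDIDATES) * bw_g[idx],
                lo_d, hi_d)
            draws = np.where(comp == len(good), from_prior, from_kern)
            cand[:, dim] = draws
            ratio += _parzen_logpdf(draws, good[:, dim], bw_g, lo_d, hi_d)
            ratio -= _parzen_logpdf(draws, bad[:, dim], bw_b, lo_d, hi_d)
        k = int(np.argmax(ratio))
        evaluate(i, cand[k, 0], cand[k, 1])
    return params, scores, span


def tpe_search(exposures, benefit, n_trials: int = 200,
               seed: int = 0) -> TherapeuticWindow:
    """Sequential TPE maximization of the concordance objective.

    Searches the continuous (lower, width) space with uniform priors over
    the exposure range, splitting ``n_trials`` over two independent runs;
    fully reproducible given ``seed``.  Ties among equal-objective trials
    are broken toward the widest window, then the lowest lower bound.
    """
    if n_trials < MIN_TRIALS:
        raise InvalidWindowError(f"n_trials must be >= {MIN_TRIALS}, got {n_trials}")
    x = np.asarray(exposures, dtype=float)
    b = np.asarray(benefit, dtype=bool)
    if np.unique(x).size < 2:
        raise InvalidWindowError("need at least 2 distinct exposure values")
    rng = np.random.default_rng(seed)

    all_params, all_scores = [], []
    per_run = n_trials // TPE_RESTARTS
    budgets = [per_run] * (TPE_RESTARTS - 1) + [n_trials - per_run * (TPE_RESTARTS - 1)]
    for budget in budgets:
        p, s, span = _tpe_run(x, b, budget, rng)
        all_params.append(p)
        all_scores.append(s)
    params = np.vstack(all_params)
    scores = np.concatenate(all_scores)

    key = scores.astype(float) + params[:, 1] / span * 1e-4 - params[:, 0] / span * 1e-8
    ib = int(np.argmax(key))
    lower, width = params[ib]
    upper = lower + width
    n_inside = int(np.sum((x >= lower) & (x <= upper)))
    return TherapeuticWindow(lower=float(lower), upper=float(upper),
                             objective=int(scores[ib]), n_inside=n_inside,
                             n_outside=x.size - n_inside)


# ---------------------------------------------------------------------------
# contingency summaries
# ---------------------------------------------------------------------------

def contingency(window: TherapeuticWindow, exposures,
                outcomes: dict) -> ContingencySummary:
    """2x2 counts per outcome flag list, inside vs outside the window.

    ``outcomes`` maps an outcome name (e.g. "nephrotoxicity", "efficacy",
    "clinical_benefit") to a boolean list aligned with ``exposures``.
    """
    x = np.asarray(exposures, dtype=float)
    inside = window.contains(x)
    tables = {}
    for name, flags in outcomes.items():
        f = np.asarray(flags, dtype=bool)
        if f.shape != x.shape:
            raise ValueError(f"outcome {name!r} length mismatch")
        tables[name] = {
            "yes_inside": int(np.sum(f & inside)),
            "no_inside": int(np.sum(~f & inside)),
            "yes_outside": int(np.sum(f & ~inside)),
            "no_outside": int(np.sum(~f & ~inside)),
        }
    return ContingencySummary(n_inside=int(inside.sum()),
                              n_outside=int((~inside).sum()), tables=tables)
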