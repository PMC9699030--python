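"""End-to-end study orchestration, input validation and the CLI.

Stages: load + validate the five input tables, Bayesian-fit every patient,
summarize exposure over the first three courses, search the therapeutic
window on the chosen exposure metric, benchmark the classifier families
with permutation importance, and propose next-course doses toward the
window midpoint.  Artifacts (fits.csv, exposure.csv, window.json,
contingency.csv, scores.csv, importance.csv, proposals.csv, run_log.json)
are written to the output directory; a single master seed determines every
stochastic stage, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import bayesfit, cohort, dosing, mlbench, synth, window as window_mod
from .dosing import DEFAULT_TARGET_CMAX as DEFAULT_TARGET
from .pkcore import CISPLATIN_POPULATION, DosingEvent

__all__ = [
    "StudyConfig",
    "SchemaError",
    "validate_inputs",
    "run_study",
    "cli",
]

log = logging.getLogger("cisdose")

REQUIRED_COLUMNS = {
    "patients": ["patient_id", "age", "sex", "weight_kg", "bsa_m2",
                 "baseline_creatinine"],
    "courses": ["patient_id", "course_index", "dose_mg", "start_h",
                "duration_h"],
    "levels": ["patient_id", "course_index", "time_h", "concentration_ug_ml",
               "kind"],
    "outcomes": ["patient_id", "recist_class"],
    "creatinine": ["patient_id", "course_index", "value"],
}


class SchemaError(ValueError):
    """Input tables violate the expected schemas."""


@dataclass(frozen=True)
class StudyConfig:
    """Paths, stage settings and the master seed for one full run."""

    patients_csv: str = "patients.csv"
    courses_csv: str = "courses.csv"
    levels_csv: str = "levels.csv"
    outcomes_csv: str = "outcomes.csv"
    creatinine_csv: str = "creatinine.csv"
    out_dir: str = "results"
    seed: int = 0
    # prior / residual model
    omega_coeff: float = 0.3
    omega_rate: float = 0.2
    sigma_prop: float = 0.15
    sigma_add: float = 0.05
    # window search
    window_metric: str = "cmax_mean"
    window_step: float = 0.1
    window_trials: int = 200
    # ML harness
    train_fraction: float = 0.7
    cv_folds: int = 5
    search_budget: int = 20
    # dosing
    target_cmax: float | None = None    #: None -> mid-window of the search
    spacing_h: float = 21 * 24.0

    def prior(self) -> bayesfit.PriorModel:
        return bayesfit.PriorModel(
            population=CISPLATIN_POPULATION,
            omega=(self.omega_coeff,) * 3 + (self.omega_rate,) * 3,
            sigma_prop=self.sigma_prop, sigma_add=self.sigma_add,
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

def _read_csv(path: str) -> pd.DataFrame:
    p = Path(path)
    if not p.exists():
        raise IOError(f"cannot read input file: {p}")
    return pd.read_csv(p)


def validate_inputs(paths: dict) -> list[dict]:
    """Schema-check the input tables; returns one entry per violation.

    Each entry has ``file``, ``row`` (or None), ``column`` (or None),
    ``severity`` ("error" | "warning") and ``message``.  Gap-free course
    indices are not required (gaps warn, they do not fail).
    """
    report: list[dict] = []

    def add(file, row, column, severity, message):
        report.append({"file": file, "row": row, "column": column,
                       "severity": severity, "message": message})

    frames = {}
    for name, path in paths.items():
        df = _read_csv(path)
        frames[name] = df
        for col in REQUIRED_COLUMNS.get(name, []):
            if col not in df.columns:
                add(name, None, col, "error", f"missing required column {col!r}")

    lv = frames.get("levels")
    if lv is not None and "concentration_ug_ml" in lv.columns:
        for i, v in lv["concentration_ug_ml"].items():
            if not np.isfinite(v) or v < 0:
                add("levels", int(i), "concentration_ug_ml", "error",
                    f"invalid concentration {v!r}")
        if "kind" in lv.columns:
            bad = ~lv["kind"].isin(["trough", "peak"])
            for i in lv.index[bad]:
                add("levels", int(i), "kind", "error",
                    f"unknown sample kind {lv.loc[i, 'kind']!r}")

    co = frames.get("courses")
    if co is not None and {"patient_id", "course_index"} <= set(co.columns):
        for pid, grp in co.groupby("patient_id"):
            idx = sorted(grp["course_index"].tolist())
            if idx != list(range(idx[0], idx[0] + len(idx))):
                add("courses", None, "course_index", "warning",
                    f"patient {pid}: course indices {idx} have gaps")
            if "dose_mg" in grp.columns and (grp["dose_mg"] < 0).any():
                add("courses", None, "dose_mg", "error",
                    f"patient {pid}: negative dose")
            if "start_h" in grp.columns:
                starts = grp.sort_values("course_index")["start_h"].values
                if not np.all(np.diff(starts) > 0):
                    add("courses", None, "start_h", "error",
                        f"patient {pid}: course starts not increasing")

    # peak-after-trough ordering within each patient-course
    if lv is not None and co is not None and \
            {"patient_id", "course_index", "time_h", "kind"} <= set(lv.columns):
        for (pid, ci), grp in lv.groupby(["patient_id", "course_index"]):
            tr = grp.loc[grp["kind"] == "trough", "time_h"]
            pk = grp.loc[grp["kind"] == "peak", "time_h"]
            if len(tr) and len(pk) and pk.min() <= tr.max():
                add("levels", None, "time_h", "error",
                    f"patient {pid} course {ci}: peak sampled before trough")

    oc = frames.get("outcomes")
    if oc is not None and "recist_class" in oc.columns:
        bad = ~oc["recist_class"].isin(cohort.RECIST_CLASSES)
        for i in oc.index[bad]:
            add("outcomes", int(i), "recist_class", "error",
                f"unknown RECIST class {oc.loc[i, 'recist_class']!r}")
    return report


# ---------------------------------------------------------------------------
# study stages
# ---------------------------------------------------------------------------

def _load_tables(config: StudyConfig) -> dict[str, pd.DataFrame]:
    paths = {"patients": config.patients_csv, "courses": config.courses_csv,
             "levels": config.levels_csv, "outcomes": config.outcomes_csv,
             "creatinine": config.creatinine_csv}
    report = validate_inputs(paths)
    errors = [r for r in report if r["severity"] == "error"]
    for r in report:
        log.log(logging.ERROR if r["severity"] == "error" else logging.WARNING,
                "%s: %s", r["file"], r["message"])
    if errors:
        raise SchemaError(f"{len(errors)} schema violation(s); aborting "
                          "before computation")
    return {k: _read_csv(v) for k, v in paths.items()}


def fit_stage(tables: dict, config: StudyConfig) -> tuple[pd.DataFrame, dict]:
    """MAP-fit every patient from their full dosing + sampling history."""
    prior = config.prior()
    fits = {}
    for pid, course_grp in tables["courses"].groupby("patient_id", sort=True):
        regimen = [DosingEvent(r.dose_mg, r.start_h, r.duration_h)
                   for r in course_grp.sort_values("course_index").itertuples()]
        lv = tables["levels"]
        obs = bayesfit.observations_from_frame(
            lv[lv.patient_id == pid].sort_values("time_h"))
        try:
            fit = bayesfit.map_estimate(prior, obs, regimen, seed=config.seed)
        except (bayesfit.DegenerateDataError, ValueError) as exc:
            log.warning("patient %s: fit skipped (%s)", pid, exc)
            continue
        if fit.blq_imputed:
            log.warning("patient %s: %d observation(s) below LLOQ imputed",
                        pid, fit.blq_imputed)
        if not fit.accepted:
            log.warning("patient %s: precision acceptance failed "
                        "(max rel SE %.2f)", pid, float(np.max(fit.rel_se)))
        fits[pid] = fit
    return bayesfit.fits_to_frame(fits), fits


def exposure_stage(tables: dict, fits: dict, config: StudyConfig) -> pd.DataFrame:
    rows = []
    for pid, fit in fits.items():
        grp = tables["courses"][tables["courses"].patient_id == pid]
        regimen = [DosingEvent(r.dose_mg, r.start_h, r.duration_h)
                   for r in grp.sort_values("course_index").itertuples()]
        lv = tables["levels"]
        obs = bayesfit.observations_from_frame(lv[lv.patient_id == pid])
        m = cohort.exposure_summary([fit], regimen, obs)
        rows.append({"patient_id": pid, "cmax_mean": m.cmax_mean,
                     "cmin_mean": m.cmin_mean, "auc_mean": m.auc_mean})
    return pd.DataFrame(rows)


def outcome_stage(tables: dict) -> pd.DataFrame:
    """Toxicity rules + composite benefit per patient."""
    crea = tables["creatinine"]
    base = tables["patients"].set_index("patient_id")["baseline_creatinine"]
    oc = tables["outcomes"].set_index("patient_id")
    rows = []
    for pid in oc.index:
        series = crea.loc[crea.patient_id == pid].sort_values("course_index")[
            "value"].tolist()
        nephro = cohort.nephrotoxicity_flag(float(base[pid]), series)
        if "ototox_severe" in oc.columns:
            oto = bool(oc.loc[pid, "ototox_severe"])
        elif "ototox_grade" in oc.columns:
            oto = int(oc.loc[pid, "ototox_grade"]) >= 3
        else:
            oto = False
        recist = str(oc.loc[pid, "recist_class"])
        rows.append({
            "patient_id": pid, "recist_class": recist,
            "nephrotoxicity_severe": nephro, "ototoxicity_severe": oto,
            "efficacy": recist in ("CR", "PR", "SD"),
            "clinical_benefit": cohort.composite_outcome(recist, nephro, oto),
        })
    return pd.DataFrame(rows)


def window_stage(exposure: pd.DataFrame, outcomes: pd.DataFrame,
                 config: StudyConfig):
    merged = exposure.merge(outcomes, on="patient_id")
    x = merged[config.window_metric].values
    b = merged["clinical_benefit"].values
    win = window_mod.tpe_search(x, b, n_trials=config.window_trials,
                                seed=config.seed)
    summary = window_mod.contingency(win, x, {
        "nephrotoxicity": merged["nephrotoxicity_severe"].values,
        "ototoxicity": merged["ototoxicity_severe"].values,
        "efficacy": merged["efficacy"].values,
        "clinical_benefit": b,
    })
    return win, summary


def contingency_frame(summary: window_mod.ContingencySummary) -> pd.DataFrame:
    rows = []
    for name, t in summary.tables.items():
        for flag in ("yes", "no"):
            rows.append({
                "outcome": name, "flag": flag,
                "inside_n": t[f"{flag}_inside"],
                "inside_pct": cohort.proportions_from_counts(
                    t[f"{flag}_inside"], summary.n_inside),
                "outside_n": t[f"{flag}_outside"],
                "outside_pct": cohort.proportions_from_counts(
                    t[f"{flag}_outside"], summary.n_outside),
            })
    return pd.DataFrame(rows)


def ml_stage(tables: dict, exposure: pd.DataFrame, outcomes: pd.DataFrame,
             config: StudyConfig):
    feats = (tables["patients"]
             .merge(exposure, on="patient_id")
             .merge(outcomes[["patient_id", "clinical_benefit"]],
                    on="patient_id"))
    table = mlbench.preprocess(feats)
    idx_train, idx_test = mlbench.stratified_split(
        table, config.train_fraction, seed=config.seed)
    # scaling must come from the training partition only
    table = mlbench.preprocess(feats, fit_index=idx_train)
    scores, fitted = mlbench.benchmark(
        table.X.loc[idx_train], table.y.loc[idx_train],
        table.X.loc[idx_test], table.y.loc[idx_test],
        cv_folds=config.cv_folds, search_budget=config.search_budget,
        seed=config.seed)
    best = scores.loc[scores.best, "model"].iloc[0]
    importance = mlbench.permutation_importance(
        fitted[best], table.X.loc[idx_test], table.y.loc[idx_test],
        seed=config.seed)
    return scores, importance


def dosing_stage(tables: dict, fits: dict, target: float,
                 config: StudyConfig) -> pd.DataFrame:
    rows = []
    for pid, fit in fits.items():
        grp = tables["courses"][tables["courses"].patient_id == pid]
        regimen = [DosingEvent(r.dose_mg, r.start_h, r.duration_h)
                   for r in grp.sort_values("course_index").itertuples()]
        next_start = regimen[-1].start + config.spacing_h
        prop = dosing.propose_dose(fit, regimen, next_start,
                                   target=target,
                                   actual_dose=regimen[-1].dose, force=True)
        if not prop.feasible:
            log.warning("patient %s: residual alone exceeds the target; "
                        "infeasible proposal", pid)
        rows.append({
            "patient_id": pid, "actual_dose_mg": prop.actual_dose,
            "proposed_dose_mg": prop.proposed_dose,
            "percent_change": prop.percent_change,
            "predicted_trough_d21": prop.predicted_trough_d21,
            "target_cmax": prop.target_cmax, "feasible": prop.feasible,
        })
    return pd.DataFrame(rows)


def run_study(config: StudyConfig) -> dict[str, Path]:
    """Execute fit -> exposure -> (window, ML) -> dosing; write all artifacts.

    Returns the artifact paths.  Stages already completed keep their
    outputs on a later-stage failure.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def write_csv(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        artifacts[name] = path

    tables = _load_tables(config)
    fits_frame, fits = fit_stage(tables, config)
    write_csv("fits.csv", fits_frame)

    exposure = exposure_stage(tables, fits, config)
    write_csv("exposure.csv", exposure)
    outcomes = outcome_stage(tables)

    win, summary = window_stage(exposure, outcomes, config)
    (out / "window.json").write_text(json.dumps(win.as_dict(), indent=2))
    artifacts["window.json"] = out / "window.json"
    write_csv("contingency.csv", contingency_frame(summary))

    scores, importance = ml_stage(tables, exposure, outcomes, config)
    write_csv("scores.csv", scores)
    write_csv("importance.csv", importance)

    target = config.target_cmax
    if target is None:
        target = 0.5 * (win.lower + win.upper)
    write_csv("proposals.csv", dosing_stage(tables, fits, target, config))

    run_log = {
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_patients": int(tables["patients"].shape[0]),
        "n_fits": len(fits),
        "window": win.as_dict(),
        "target_cmax": target,
        "artifacts": sorted(artifacts),
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
    artifacts["run_log.json"] = out / "run_log.json"
    return artifacts


# ---------------------------------------------------------------------------
# command-line interface
# ---------------------------------------------------------------------------

def _config_from(path: str | None, **overrides) -> StudyConfig:
    values = {}
    if path:
        import yaml
        values.update(yaml.safe_load(Path(path).read_text()) or {})
    values.update({k: v for k, v in overrides.items() if v is not None})
    return StudyConfig(**values)


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Log at DEBUG level.")
def cli(verbose: bool) -> None:
    """Model-informed precision dosing for 3-hour cisplatin infusions."""
    logging.basicConfig(stream=sys.stderr,
                        level=logging.DEBUG if verbose else logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")


@cli.command()
@click.option("--n-patients", default=80, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "out_dir", default="synthetic", show_default=True)
def simulate(n_patients: int, seed: int, out_dir: str) -> None:
    """Generate a synthetic cohort and write its CSV tables."""
    records, truth = synth.generate_cohort(
        synth.SynthConfig(n_patients=n_patients, seed=seed))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, frame in synth.cohort_to_frames(records, truth).items():
        frame.to_csv(out / f"{name}.csv", index=False, float_format="%.10g")
    click.echo(f"wrote {n_patients}-patient cohort to {out}/")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--data", "data_dir", default="synthetic", show_default=True)
@click.option("--seed", type=int, default=None)
@click.option("--out", "out_dir", default=None)
@click.option("--target-cmax", type=float, default=None)
@click.option("--window-step", type=float, default=None)
@click.option("--trials", "window_trials", type=int, default=None)
@click.option("--train-fraction", type=float, default=None)
def run(config_path, data_dir, seed, out_dir, target_cmax, window_step,
        window_trials, train_fraction) -> None:
    """Run the full pipeline on a data directory."""
    cfg = _config_from(
        config_path,
        patients_csv=f"{data_dir}/patients.csv",
        courses_csv=f"{data_dir}/courses.csv",
        levels_csv=f"{data_dir}/levels.csv",
        outcomes_csv=f"{data_dir}/outcomes.csv",
        creatinine_csv=f"{data_dir}/creatinine.csv",
        seed=seed, out_dir=out_dir, target_cmax=target_cmax,
        window_step=window_step, window_trials=window_trials,
        train_fraction=train_fraction,
    )
    artifacts = run_study(cfg)
    for name in sorted(artifacts):
        click.echo(f"wrote {artifacts[name]}")


def _stage_config(data_dir: str, seed: int, out_dir: str, **kw) -> StudyConfig:
    return StudyConfig(
        patients_csv=f"{data_dir}/patients.csv",
        courses_csv=f"{data_dir}/courses.csv",
        levels_csv=f"{data_dir}/levels.csv",
        outcomes_csv=f"{data_dir}/outcomes.csv",
        creatinine_csv=f"{data_dir}/creatinine.csv",
        seed=seed, out_dir=out_dir, **kw)


def _stage_common(f):
    f = click.option("--data", "data_dir", default="synthetic",
                     show_default=True)(f)
    f = click.option("--seed", type=int, default=0, show_default=True)(f)
    f = click.option("--out", "out_dir", default="results",
                     show_default=True)(f)
    return f


@cli.command()
@_stage_common
def fit(data_dir, seed, out_dir) -> None:
    """Bayesian-fit every patient and write fits.csv."""
    cfg = _stage_config(data_dir, seed, out_dir)
    tables = _load_tables(cfg)
    frame, _ = fit_stage(tables, cfg)
    Path(out_dir).mkdir(parents=True, exist_ok=True)
    frame.to_csv(Path(out_dir) / "fits.csv", index=False, float_format="%.10g")
    click.echo(f"wrote {out_dir}/fits.csv ({len(frame)} fits)")


@cli.command()
@_stage_common
def exposure(data_dir, seed, out_dir) -> None:
    """Compute per-patient exposure metrics and write exposure.csv."""
    cfg = _stage_config(data_dir, seed, out_dir)
    tables = _load_tables(cfg)
    _, fits = fit_stage(tables, cfg)
    frame = exposure_stage(tables, fits, cfg)
    Path(out_dir).mkdir(parents=True, exist_ok=True)
    frame.to_csv(Path(out_dir) / "exposure.csv", index=False,
                 float_format="%.10g")
    click.echo(f"wrote {out_dir}/exposure.csv")


@cli.command(name="window")
@_stage_common
@click.option("--trials", type=int, default=200, show_default=True)
@click.option("--metric", default="cmax_mean", show_default=True)
def window_cmd(data_dir, seed, out_dir, trials, metric) -> None:
    """Search the therapeutic window and write window.json + contingency.csv."""
    cfg = _stage_config(data_dir, seed, out_dir, window_trials=trials,
                        window_metric=metric)
    tables = _load_tables(cfg)
    _, fits = fit_stage(tables, cfg)
    expo = exposure_stage(tables, fits, cfg)
    outcomes = outcome_stage(tables)
    win, summary = window_stage(expo, outcomes, cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "window.json").write_text(json.dumps(win.as_dict(), indent=2))
    contingency_frame(summary).to_csv(out / "contingency.csv", index=False)
    click.echo(f"window [{win.lower:.2f}, {win.upper:.2f}] ug/mL, "
               f"objective {win.objective}")


@cli.command(name="mlbench")
@_stage_common
@click.option("--budget", type=int, default=20, show_default=True)
def mlbench_cmd(data_dir, seed, out_dir, budget) -> None:
    """Benchmark the classifier families; write scores.csv + importance.csv."""
    cfg = _stage_config(data_dir, seed, out_dir, search_budget=budget)
    tables = _load_tables(cfg)
    _, fits = fit_stage(tables, cfg)
    expo = exposure_stage(tables, fits, cfg)
    outcomes = outcome_stage(tables)
    scores, importance = ml_stage(tables, expo, outcomes, cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scores.to_csv(out / "scores.csv", index=False, float_format="%.10g")
    importance.to_csv(out / "importance.csv", index=False,
                      float_format="%.10g")
    click.echo(scores[["model", "accuracy", "recall", "precision"]]
               .to_string(index=False))


@cli.command(name="dose")
@_stage_common
@click.option("--target-cmax", type=float, default=DEFAULT_TARGET)
def dose_cmd(data_dir, seed, out_dir, target_cmax) -> None:
    """Propose next-course doses toward a target peak; write proposals.csv."""
    cfg = _stage_config(data_dir, seed, out_dir)
    tables = _load_tables(cfg)
    _, fits = fit_stage(tables, cfg)
    frame = dosing_stage(tables, fits, target_cmax, cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out / "proposals.csv", index=False, float_format="%.10g")
    click.echo(f"wrote {out_dir}/proposals.csv")


@cli.command()
@click.option("--data", "data_dir", default="synthetic", show_default=True)
def validate(data_dir: str) -> None:
    """Validate input tables against the expected schemas."""
    paths = {name: f"{data_dir}/{name}.csv"
             for name in ("patients", "courses", "levels", "outcomes",
                          "creatinine")}
    report = validate_inputs(paths)
    if not report:
        click.echo("0 violations")
        return
    for r in report:
        click.echo(f"{r['severity'].upper()} {r['file']}"
                   f"[row={r['row']}, col={r['column']}]: {r['message']}")
    if any(r["severity"] == "error" for r in report):
        raise SystemExit(1)
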