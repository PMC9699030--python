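"""Linear three-compartment disposition model for cisplatin infusions.

The plasma concentration after an intravenous bolus of a drug with
mammillary three-compartment kinetics is a tri-exponential,

    C(t) = dose * (A e^{-alpha t} + B e^{-beta t} + C e^{-gamma t}),

where the macro-coefficients A, B, C carry units of 1/L (per mg of dose,
so dose[mg] * coefficient[1/L] -> mg/L = ug/mL) and alpha > beta > gamma
are the exponential rate constants.  Zero-order (constant-rate) infusion
input and multi-dose superposition follow from linearity and have closed
forms, so no numerical integration is needed anywhere in the pipeline;
an ODE integration of the equivalent micro-constant system serves as an
independent oracle in the test-suite only.

Units: concentrations ug/mL (= mg/L), doses mg, times hours.  The
reference population rate constants for cisplatin are interpreted as
h^-1 by default: that reading reproduces the cohort-scale clearance
(~4.2 L/h), AUC (~42 ug.h/mL) and end-of-infusion peak (~3.3 ug/mL) of a
164 mg, 3-hour infusion, whereas a literal day^-1 reading is off by more
than an order of magnitude.  A ``time_unit`` field preserves the literal
reading for sensitivity analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PopulationPK",
    "DosingEvent",
    "MicroPK",
    "DerivedPK",
    "CISPLATIN_POPULATION",
    "InvalidRegimenError",
    "NonIdentifiableModelError",
    "unit_infusion_response",
    "simulate_profile",
    "macro_to_micro",
    "micro_to_macro",
    "derived_params",
    "auc_for_dose",
]

#: relative separation below which two exponential rates are treated as
#: coincident (the macro->micro conversion is then ill-conditioned)
RATE_SEPARATION_TOL = 1e-9

HOURS_PER_DAY = 24.0


class InvalidRegimenError(ValueError):
    """A dosing event or query violates the regimen contract."""


class NonIdentifiableModelError(ValueError):
    """Macro constants do not map to a valid micro-constant system."""


@dataclass(frozen=True)
class PopulationPK:
    """Tri-exponential macro parameterization of a three-compartment model.

    Parameters
    ----------
    A, B, C : float
        Macro-coefficients per unit dose (1/L); positive.
    alpha, beta, gamma : float
        Exponential rate constants, strictly ordered alpha > beta > gamma > 0.
    time_unit : {"h", "day"}
        Declared unit of the rate constants.  All model evaluation is done
        in hours; ``day`` rates are converted on access.
    """

    A: float
    B: float
    C: float
    alpha: float
    beta: float
    gamma: float
    time_unit: str = "h"

    def __post_init__(self) -> None:
        if self.time_unit not in ("h", "day"):
            raise ValueError(f"time_unit must be 'h' or 'day', got {self.time_unit!r}")
        for name in ("A", "B", "C", "alpha", "beta", "gamma"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        lam = np.array([self.alpha, self.beta, self.gamma])
        if not (lam[0] > lam[1] > lam[2]):
            raise ValueError("rate constants must satisfy alpha > beta > gamma")
        sep = np.min(-np.diff(lam) / lam[:-1])
        if sep <= RATE_SEPARATION_TOL:
            raise NonIdentifiableModelError(
                f"rate constants too close (relative separation {sep:.2e} <= "
                f"{RATE_SEPARATION_TOL:.0e})"
            )

    @property
    def coefficients(self) -> np.ndarray:
        """Macro-coefficients (A, B, C) as an array, 1/L."""
        return np.array([self.A, self.B, self.C])

    @property
    def rates_per_hour(self) -> np.ndarray:
        """Rate constants (alpha, beta, gamma) in h^-1 regardless of time_unit."""
        lam = np.array([self.alpha, self.beta, self.gamma])
        if self.time_unit == "day":
            lam = lam / HOURS_PER_DAY
        return lam

    def with_macros(self, macros: np.ndarray) -> "PopulationPK":
        """New parameter set from a 6-vector (A, B, C, alpha, beta, gamma)."""
        return PopulationPK(*map(float, macros), time_unit=self.time_unit)

    def as_dict(self) -> dict:
        return {
            "A": self.A, "B": self.B, "C": self.C,
            "alpha": self.alpha, "beta": self.beta, "gamma": self.gamma,
            "time_unit": self.time_unit,
        }


#: Reference cisplatin population macro parameters from rich sampling in
#: adult head-and-neck cancer patients (rates read as h^-1, see module doc).
CISPLATIN_POPULATION = PopulationPK(
    A=0.008106, B=0.008095, C=0.006742,
    alpha=0.5113, beta=0.07893, gamma=0.05439,
    time_unit="h",
)


@dataclass(frozen=True)
class DosingEvent:
    """One intravenous infusion: ``dose`` mg over ``duration`` h from ``start`` h."""

    dose: float
    start: float
    duration: float = 3.0

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise InvalidRegimenError(f"dose must be >= 0, got {self.dose}")
        if self.duration <= 0:
            raise InvalidRegimenError(f"duration must be > 0, got {self.duration}")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class MicroPK:
    """Micro-constant parameterization: central volume and transfer rates."""

    V1: float
    k10: float
    k12: float
    k21: float
    k13: float
    k31: float

    def rate_matrix(self) -> np.ndarray:
        """3x3 first-order rate matrix K with d(amounts)/dt = K @ amounts."""
        return np.array([
            [-(self.k10 + self.k12 + self.k13), self.k21, self.k31],
            [self.k12, -self.k21, 0.0],
            [self.k13, 0.0, -self.k31],
        ])


@dataclass(frozen=True)
class DerivedPK:
    """Standard secondary PK parameters derived from the macro constants."""

    CL: float                #: total clearance, L/h
    V1: float                #: central volume, L
    kel: float               #: elimination rate constant k10, 1/h
    t_half_terminal: float   #: terminal half-life ln2/gamma, h
    auc_per_mg: float        #: ug.h/mL per mg of dose


# ---------------------------------------------------------------------------
# concentration-time evaluation
# ---------------------------------------------------------------------------

def unit_infusion_response(pk: PopulationPK, duration: float, t) -> np.ndarray | float:
    """Concentration per mg of dose for a zero-order infusion starting at t=0.

    During the infusion (0 <= t <= duration) the response per mg is

        (1/T) * sum_i (A_i/lambda_i) * (1 - exp(-lambda_i t)),

    and after the end it decays as

        (1/T) * sum_i (A_i/lambda_i) * (1 - exp(-lambda_i T)) * exp(-lambda_i (t-T)).

    The expression is continuous at t = T and tends to the bolus response
    sum_i A_i exp(-lambda_i t) as T -> 0.  Negative times return 0.

    Parameters
    ----------
    pk : PopulationPK
        Macro parameter set (population or individual).
    duration : float
        Infusion duration T in hours; must be positive.
    t : float or array-like
        Time(s) from infusion start, hours.

    Returns
    -------
    float or ndarray
        Concentration in ug/mL per mg of dose.
    """
    if duration <= 0:
        raise InvalidRegimenError(f"infusion duration must be > 0, got {duration}")
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)

    lam = pk.rates_per_hour            # (3,)
    amp = pk.coefficients / lam        # A_i / lambda_i
    tt = np.clip(t_arr[:, None], 0.0, None)   # (n, 1); negatives zeroed below

    during = (amp / duration) * (1.0 - np.exp(-lam * np.minimum(tt, duration)))
    decay = np.exp(-lam * np.maximum(tt - duration, 0.0))
    out = np.sum(during * decay, axis=1)
    out[t_arr < 0] = 0.0
    return float(out[0]) if scalar else out


def simulate_profile(pk: PopulationPK, regimen: list[DosingEvent], times) -> np.ndarray:
    """Plasma concentration (ug/mL) at ``times`` under multi-dose superposition.

    Linearity of the kinetics means every infusion contributes
    ``dose * unit_infusion_response`` shifted to its start time; overlapping
    events simply add.  Full residual history is always carried (no
    steady-state shortcut) because course intervals vary in practice.
    """
    t_arr = np.atleast_1d(np.asarray(times, dtype=float))
    out = np.zeros_like(t_arr)
    for ev in regimen:
        out += ev.dose * unit_infusion_response(pk, ev.duration, t_arr - ev.start)
    return out


# ---------------------------------------------------------------------------
# macro <-> micro conversion
# ---------------------------------------------------------------------------

def macro_to_micro(pk: PopulationPK) -> MicroPK:
    """Convert macro constants to the micro-constant system.

    With dose-normalised macros, V1 = 1/(A+B+C).  The peripheral return
    rates k21, k31 are the roots of x^2 - S x + P = 0 with

        S = [A(beta+gamma) + B(alpha+gamma) + C(alpha+beta)] / (A+B+C)
        P = (A beta gamma + B alpha gamma + C alpha beta) / (A+B+C),

    after which k10 = alpha beta gamma / (k21 k31), and k12, k13 solve the
    remaining trace / second-symmetric-function identities of the
    characteristic polynomial of the rate matrix.

    Raises
    ------
    NonIdentifiableModelError
        If the quadratic has no real roots or a root coincides with one of
        the eigenvalues (degenerate, non-mammillary macro set).
    """
    A, B, C = pk.coefficients
    alpha, beta, gamma = pk.rates_per_hour
    total = A + B + C
    V1 = 1.0 / total

    S = (A * (beta + gamma) + B * (alpha + gamma) + C * (alpha + beta)) / total
    P = (A * beta * gamma + B * alpha * gamma + C * alpha * beta) / total

    disc = S * S - 4.0 * P
    if disc < 0:
        raise NonIdentifiableModelError(
            f"complex peripheral rates (discriminant {disc:.3e} < 0)"
        )
    root = math.sqrt(disc)
    k21 = (S + root) / 2.0
    k31 = (S - root) / 2.0
    lam = np.array([alpha, beta, gamma])
    for k in (k21, k31):
        if k <= 0 or np.min(np.abs(lam - k) / lam) <= RATE_SEPARATION_TOL:
            raise NonIdentifiableModelError(
                f"peripheral rate {k:.6g} coincides with an eigenvalue or is "
                "non-positive"
            )
    k10 = alpha * beta * gamma / (k21 * k31)

    # trace: alpha+beta+gamma = k10+k12+k13+k21+k31
    # e2:    ab+ag+bg = k10(k21+k31) + k21 k31 + k12 k31 + k13 k21
    rhs1 = (alpha + beta + gamma) - k10 - k21 - k31
    rhs2 = (alpha * beta + alpha * gamma + beta * gamma) \
        - k10 * (k21 + k31) - k21 * k31
    # k12 + k13 = rhs1 ; k12*k31 + k13*k21 = rhs2  (k21 != k31 guaranteed)
    k12 = (rhs2 - k21 * rhs1) / (k31 - k21)
    k13 = rhs1 - k12
    micro = MicroPK(V1=V1, k10=k10, k12=k12, k21=k21, k13=k13, k31=k31)
    for name in ("k10", "k12", "k21", "k13", "k31"):
        if getattr(micro, name) <= 0:
            raise NonIdentifiableModelError(
                f"negative micro constant {name} = {getattr(micro, name):.6g}"
            )
    return micro


def micro_to_macro(micro: MicroPK) -> PopulationPK:
    """Inverse conversion via eigen-decomposition of the rate matrix.

    Used as the independent round-trip check of :func:`macro_to_micro`.
    """
    K = micro.rate_matrix()
    eigval, eigvec = np.linalg.eig(K)
    order = np.argsort(eigval)           # most negative first -> alpha
    lam = -eigval[order]
    V = eigvec[:, order]
    # bolus unit dose in compartment 1: amounts(t) = V exp(Lambda t) V^-1 e1
    weights = V[0, :] * np.linalg.solve(V, np.array([1.0, 0.0, 0.0]))
    coeffs = weights / micro.V1
    return PopulationPK(
        A=float(coeffs[0]), B=float(coeffs[1]), C=float(coeffs[2]),
        alpha=float(lam[0]), beta=float(lam[1]), gamma=float(lam[2]),
    )


def derived_params(pk: PopulationPK) -> DerivedPK:
    """Clearance, central volume, kel and terminal half-life from macros.

    AUC per mg of a linear system is sum_i A_i/lambda_i, hence
    CL = 1 / (A/alpha + B/beta + C/gamma); kel is the central elimination
    micro-constant k10; the terminal half-life is ln2/gamma.
    """
    lam = pk.rates_per_hour
    auc_per_mg = float(np.sum(pk.coefficients / lam))
    micro = macro_to_micro(pk)
    return DerivedPK(
        CL=1.0 / auc_per_mg,
        V1=micro.V1,
        kel=micro.k10,
        t_half_terminal=math.log(2.0) / lam[2],
        auc_per_mg=auc_per_mg,
    )


def auc_for_dose(pk: PopulationPK, dose: float) -> float:
    """Total AUC (ug.h/mL) of a dose in mg; equals dose / CL."""
    if dose < 0:
        raise InvalidRegimenError(f"dose must be >= 0, got {dose}")
    lam = pk.rates_per_hour
    return float(dose * np.sum(pk.coefficients / lam))
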