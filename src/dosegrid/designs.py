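"""Dose-selection rules and the patient-by-patient trial engine.

Two model-based designs are implemented over the same posterior:

* **CRM** (continual reassessment method): the next patient receives the
  dose whose model-estimated DLT probability is closest to the target
  theta, with the model coefficients formed by plugging posterior point
  estimates of (rho0, gamma) into the reparametrization.
* **EWOC** (escalation with overdose control): the next patient receives
  the alpha-quantile of the posterior distribution of the MTD gamma, so
  that the posterior probability of overdosing is controlled at alpha.
  The feasibility bound alpha may grow during the trial, e.g. the
  schedule C(0.05, 0.05): start at 0.05 and add 0.05 after every
  no-DLT outcome, capped at 0.50.

Discrete dose schemes additionally apply a rounding rule (nearest, ties
broken to the lower dose for safety; or round-down) and a no-skip rule:
escalation may never bypass an untried dose level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import (
    ModelParams,
    ModelSpace,
    PosteriorAccumulator,
    PosteriorGrid,
    PriorSpec,
    TrialHistory,
    canonical_from_reparam,
    gamma_posterior_mean,
    gamma_posterior_quantile,
    link_cdf,
    rho0_posterior_mean,
    DEFAULT_RESOLUTION,
)
from .truth import TruthCurve, sample_dlt

__all__ = [
    "DoseScheme",
    "FeasibilitySchedule",
    "TrialResult",
    "STUDY_SCHEMES",
    "get_scheme",
    "crm_next_dose",
    "ewoc_next_dose",
    "next_alpha",
    "apply_scheme_constraints",
    "run_trial",
]


@dataclass(frozen=True)
class DoseScheme:
    """Continuous dose interval or a finite ordered dose set."""

    mode: str  # "continuous" | "discrete"
    doses: tuple[float, ...] | None = None
    rounding: str = "nearest"
    no_skip: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("continuous", "discrete"):
            raise ValueError(f"unknown scheme mode {self.mode!r}")
        if self.rounding not in ("nearest", "down"):
            raise ValueError(f"unknown rounding rule {self.rounding!r}")
        if self.mode == "discrete":
            if not self.doses or len(self.doses) < 2:
                raise ValueError("discrete scheme needs at least two doses")
            d = np.asarray(self.doses)
            if np.any(np.diff(d) <= 0):
                raise ValueError("discrete doses must be strictly increasing")

    @classmethod
    def continuous(cls) -> "DoseScheme":
        return cls(mode="continuous")

    @classmethod
    def equally_spaced(cls, step: float, x_min: float = 0.0, x_max: float = 1.0,
                       **kwargs) -> "DoseScheme":
        doses = tuple(np.round(np.arange(x_min, x_max + step / 2, step), 10))
        return cls(mode="discrete", doses=doses, **kwargs)

    @property
    def size(self) -> int:
        if self.mode == "continuous":
            raise ValueError("continuous scheme has no finite size")
        return len(self.doses)

    def round_dose(self, raw: float) -> float:
        """Map a raw (continuous) recommendation onto the dose set."""
        if self.mode == "continuous":
            return float(raw)
        d = np.asarray(self.doses)
        if raw <= d[0]:
            return float(d[0])
        if raw >= d[-1]:
            return float(d[-1])
        hi = int(np.searchsorted(d, raw))
        lo = hi - 1
        if self.rounding == "down":
            return float(d[lo]) if raw < d[hi] else float(d[hi])
        # nearest, exact midpoint resolves to the lower dose
        return float(d[hi]) if (raw - d[lo]) > (d[hi] - raw) else float(d[lo])

    def index_of(self, dose: float) -> int:
        d = np.asarray(self.doses)
        i = int(np.argmin(np.abs(d - dose)))
        if abs(d[i] - dose) > 1e-9:
            raise ValueError(f"dose {dose} is not in the scheme")
        return i


# The six study schemes: continuous plus D0.05 (21 doses), D0.10 (11),
# D0.125 (9), D0.20 (6) and D0.25 (5).
STUDY_SCHEMES: dict[str, DoseScheme] = {
    "continuous": DoseScheme.continuous(),
    "d0.05": DoseScheme.equally_spaced(0.05),
    "d0.10": DoseScheme.equally_spaced(0.10),
    "d0.125": DoseScheme.equally_spaced(0.125),
    "d0.20": DoseScheme.equally_spaced(0.20),
    "d0.25": DoseScheme.equally_spaced(0.25),
}


def get_scheme(name: str) -> DoseScheme:
    try:
        return STUDY_SCHEMES[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown scheme {name!r}; expected one of {sorted(STUDY_SCHEMES)}"
        ) from None


@dataclass(frozen=True)
class FeasibilitySchedule:
    """Increasing feasibility bound C(alpha_init, increment) for EWOC."""

    alpha_init: float = 0.05
    increment: float = 0.05
    cap: float = 0.5
    conditional: bool = True  # advance only after a no-DLT outcome

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_init <= self.cap <= 1.0:
            raise ValueError("require 0 < alpha_init <= cap <= 1")


def next_alpha(schedule: FeasibilitySchedule, current: float, last_dlt: int) -> float:
    """Advance the feasibility bound after one patient outcome."""
    if not schedule.alpha_init <= current <= schedule.cap:
        raise ValueError(f"current alpha {current} outside schedule bounds")
    if schedule.conditional and last_dlt == 1:
        return current
    return min(current + schedule.increment, schedule.cap)


def crm_next_dose(
    grid: PosteriorGrid,
    scheme: DoseScheme,
    space: ModelSpace,
    estimator: str = "mean",
) -> float:
    """CRM recommendation: dose with estimated toxicity closest to theta.

    Plug-in coefficients are formed from posterior point estimates of
    (rho0, gamma).  In continuous mode the objective is minimized by the
    dose where the fitted curve crosses theta -- which is exactly the
    gamma estimate -- clipped to the dose interval.  In discrete mode
    the |theta - F| objective is scanned over the dose set, ties going
    to the lower dose.
    """
    if estimator == "mean":
        rho0_hat = rho0_posterior_mean(grid)
        gamma_hat = gamma_posterior_mean(grid)
    elif estimator == "median":
        rho0_hat = _rho0_posterior_median(grid)
        gamma_hat = gamma_posterior_quantile(grid, 0.5)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    if rho0_hat >= space.theta:
        raise ValueError("degenerate plug-in slope: rho0 estimate >= theta")
    if scheme.mode == "continuous":
        return float(np.clip(gamma_hat, space.x_min, space.x_max))
    coef = canonical_from_reparam(ModelParams(rho0_hat, gamma_hat), space)
    d = np.asarray(scheme.doses)
    obj = np.abs(space.theta - link_cdf(coef.beta0 + coef.beta1 * d))
    return float(d[int(np.argmin(obj))])  # argmin takes the first (lower) dose


def _rho0_posterior_median(grid: PosteriorGrid) -> float:
    w = grid.weights.sum(axis=1)
    cdf_mid = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cdf_mid, grid.rho0_nodes))


def ewoc_next_dose(grid: PosteriorGrid, alpha: float, scheme: DoseScheme) -> float:
    """EWOC recommendation: alpha-quantile of the gamma posterior,
    rounded onto the scheme in discrete mode."""
    raw = gamma_posterior_quantile(grid, alpha)
    return scheme.round_dose(raw)


def apply_scheme_constraints(
    raw: float,
    scheme: DoseScheme,
    history: TrialHistory,
    _highest_idx: int | None = None,
) -> float:
    """Round onto the scheme, then enforce the no-skip escalation rule.

    The candidate index may exceed the highest previously administered
    index by at most one; with an empty history the starting level (the
    lowest dose) is the ceiling.  De-escalation is unrestricted.
    Continuous schemes pass the raw dose through unchanged.

    ``_highest_idx`` lets the trial engine pass the highest administered
    index directly instead of re-scanning the history.
    """
    if scheme.mode == "continuous":
        return float(raw)
    dose = scheme.round_dose(raw)
    if not scheme.no_skip:
        return dose
    if _highest_idx is None:
        if len(history) == 0:
            return float(scheme.doses[0])
        _highest_idx = max(scheme.index_of(d) for d in history.doses)
    cap_idx = min(_highest_idx + 1, scheme.size - 1)
    idx = scheme.index_of(dose)
    return float(scheme.doses[min(idx, cap_idx)])


@dataclass
class TrialResult:
    """Outcome of one simulated trial."""

    history: TrialHistory
    alphas: list[float] = field(default_factory=list)
    mtd_estimate: float = float("nan")
    n: int = 0


def run_trial(
    design: str,
    truth: TruthCurve,
    scheme: DoseScheme,
    n: int,
    rng: np.random.Generator,
    schedule: FeasibilitySchedule | None = None,
    prior: PriorSpec | None = None,
    space: ModelSpace | None = None,
    resolution: Sequence[int] = DEFAULT_RESOLUTION,
    estimator: str = "mean",
    cohort_size: int = 1,
) -> TrialResult:
    """Simulate one adaptive trial patient by patient.

    The first cohort receives the lowest dose.  Each subsequent cohort's
    dose is computed from the current posterior (per the design rule),
    constrained by the scheme (rounding + no-skip), and the binary DLT
    outcome is drawn from the truth curve.  The final MTD estimate is
    the posterior mean of gamma after n patients.
    """
    design = design.lower()
    if design not in ("crm", "ewoc"):
        raise ValueError(f"unknown design {design!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    space = space or ModelSpace(theta=truth.theta, x_min=truth.x_min, x_max=truth.x_max)
    prior = prior or PriorSpec()
    schedule = schedule or FeasibilitySchedule()

    acc = PosteriorAccumulator(prior, space, resolution)
    history = TrialHistory()
    alphas: list[float] = []
    alpha = schedule.alpha_init
    start_dose = space.x_min if scheme.mode == "continuous" else float(scheme.doses[0])

    treated = 0
    highest_idx = 0  # highest administered dose index (discrete schemes)
    while treated < n:
        if treated == 0:
            dose = start_dose
        else:
            grid = acc.grid()
            if design == "crm":
                raw = crm_next_dose(grid, scheme, space, estimator=estimator)
            else:
                raw = gamma_posterior_quantile(grid, alpha)
            dose = apply_scheme_constraints(raw, scheme, history, _highest_idx=highest_idx)
        if scheme.mode == "discrete":
            highest_idx = max(highest_idx, scheme.index_of(dose))
        for _ in range(min(cohort_size, n - treated)):
            dlt = sample_dlt(truth, dose, rng)
            history.append(dose, dlt)
            acc.add(dose, dlt)
            alphas.append(alpha)
            if design == "ewoc":
                alpha = next_alpha(schedule, alpha, dlt)
            treated += 1

    estimate = gamma_posterior_mean(acc.grid())
    return TrialResult(history=history, alphas=alphas, mtd_estimate=estimate, n=n)
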