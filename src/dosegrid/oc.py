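"""Operating characteristics: optimality intervals and trial summaries.

Two notions of an "optimal dose" are used to score a design:

* the **optimal MTD interval** — doses within a relative window around
  the true MTD, (gamma (1 - delta), gamma (1 + delta)) with delta = 0.15
  by default;
* the **optimal toxicity interval** — doses whose *true* DLT probability
  lies within a band around the target, (theta - band, theta + band)
  with band = 0.10 by default, inverted through the truth curve.

Both intervals are open (strict inequalities).  Per-scenario summaries
report bias and RMSE of the MTD estimate, the average DLT rate, the
percentage of trials whose observed DLT proportion falls inside the
target band, and trial- and patient-level optimality percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .designs import DoseScheme, STUDY_SCHEMES, TrialResult
from .model import ModelSpace
from .truth import (
    STUDY_MTDS,
    STUDY_SHAPES,
    TruthCurve,
    calibrate_truth,
    _lookup_rho0,
)

__all__ = [
    "OptimalInterval",
    "OCSummary",
    "optimal_mtd_interval",
    "optimal_toxicity_interval",
    "count_optimal_doses",
    "round_percent",
    "summarize_trials",
    "optimal_mtd_table",
    "optimal_toxicity_table",
]

DEFAULT_MTD_DELTA = 0.15
DEFAULT_TOX_BAND = 0.10
DEFAULT_DLT_BAND = 0.10


@dataclass(frozen=True)
class OptimalInterval:
    """Dose interval used to score recommendations.

    Endpoints are open (strict inequalities), matching the defining
    inequalities of both optimality criteria.  An endpoint becomes
    closed only when it is a clip at the dose boundary rather than a
    solution of the defining inequality: there the boundary dose itself
    satisfies the (strict) toxicity inequality.
    """

    lower: float
    upper: float
    kind: str  # "mtd_relative" | "toxicity_band"
    closed_lower: bool = False
    closed_upper: bool = False

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(
                f"degenerate interval: lower {self.lower} must be < upper {self.upper}"
            )

    def contains(self, x) -> np.ndarray:
        x = np.asarray(x)
        lo = (x >= self.lower) if self.closed_lower else (x > self.lower)
        hi = (x <= self.upper) if self.closed_upper else (x < self.upper)
        return lo & hi


def optimal_mtd_interval(gamma_true: float, delta: float = DEFAULT_MTD_DELTA) -> OptimalInterval:
    """Relative window around the true MTD: (gamma(1-delta), gamma(1+delta))."""
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    return OptimalInterval(
        lower=gamma_true * (1.0 - delta),
        upper=gamma_true * (1.0 + delta),
        kind="mtd_relative",
    )


def optimal_toxicity_interval(
    truth: TruthCurve, band: float = DEFAULT_TOX_BAND
) -> OptimalInterval:
    """Dose window whose true toxicity lies in (theta - band, theta + band).

    Obtained by monotone inversion of the truth curve and intersected
    with the standardized dose interval.
    """
    theta = truth.theta
    if not 0.0 < band < min(theta, 1.0 - theta):
        raise ValueError(f"band must lie in (0, min(theta, 1-theta)), got {band}")
    lo_p, hi_p = theta - band, theta + band
    clip_lo = lo_p < truth.prob(truth.x_min)
    clip_hi = hi_p > truth.prob(truth.x_max)
    lower = truth.x_min if clip_lo else truth.inverse_prob(lo_p)
    upper = truth.x_max if clip_hi else truth.inverse_prob(hi_p)
    return OptimalInterval(
        lower=float(max(lower, truth.x_min)),
        upper=float(min(upper, truth.x_max)),
        kind="toxicity_band",
        closed_lower=bool(clip_lo),
        closed_upper=bool(clip_hi),
    )


def round_percent(value: float) -> float:
    """Percentages reported to one decimal, half-up."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def count_optimal_doses(
    scheme: DoseScheme, interval: OptimalInterval
) -> tuple[int, float]:
    """(count, percent of scheme size) of scheme doses strictly inside."""
    if scheme.mode != "discrete":
        raise ValueError("optimal-dose counting applies to discrete schemes only")
    count = int(interval.contains(np.asarray(scheme.doses)).sum())
    return count, round_percent(100.0 * count / scheme.size)


@dataclass(frozen=True)
class OCSummary:
    """Per-scenario operating characteristics over replicated trials."""

    bias: float
    rmse: float
    mean_dlt_rate: float
    pct_trials_dlt_in_band: float
    pct_trials_mtd_in_interval: Mapping[str, float]
    pct_patients_optimal: Mapping[str, float]
    replicates: int

    def __post_init__(self) -> None:
        if self.rmse < abs(self.bias) - 1e-12:
            raise ValueError("RMSE cannot be smaller than |bias|")


def summarize_trials(
    results: Sequence[TrialResult],
    truth: TruthCurve,
    intervals: Mapping[str, OptimalInterval],
    dlt_band: float = DEFAULT_DLT_BAND,
) -> OCSummary:
    """Aggregate replicated trials of one scenario into an OCSummary."""
    if not results:
        raise ValueError("need at least one trial result")
    ns = {r.n for r in results}
    if len(ns) > 1:
        raise ValueError(f"mixed sample sizes in one scenario: {sorted(ns)}")

    estimates = np.array([r.mtd_estimate for r in results])
    err = estimates - truth.gamma_true
    bias = float(err.mean())
    rmse = float(np.sqrt(np.mean(err**2)))

    dlt_props = np.array([r.history.dlts.mean() for r in results])
    mean_dlt_rate = float(dlt_props.mean())
    in_band = np.abs(dlt_props - truth.theta) < dlt_band
    pct_dlt_band = 100.0 * float(in_band.mean())

    pct_mtd = {
        kind: 100.0 * float(iv.contains(estimates).mean())
        for kind, iv in intervals.items()
    }
    pct_patients = {
        kind: 100.0
        * float(np.mean([iv.contains(r.history.doses).mean() for r in results]))
        for kind, iv in intervals.items()
    }
    return OCSummary(
        bias=bias,
        rmse=rmse,
        mean_dlt_rate=mean_dlt_rate,
        pct_trials_dlt_in_band=pct_dlt_band,
        pct_trials_mtd_in_interval=pct_mtd,
        pct_patients_optimal=pct_patients,
        replicates=len(results),
    )


_DISCRETE_SCHEME_NAMES = ("d0.05", "d0.10", "d0.125", "d0.20", "d0.25")
_SCHEME_LABELS = {
    "d0.05": "D0.05",
    "d0.10": "D0.10",
    "d0.125": "D0.125",
    "d0.20": "D0.20",
    "d0.25": "D0.25",
}


def optimal_mtd_table(
    delta: float = DEFAULT_MTD_DELTA,
    mtds: Sequence[float] = STUDY_MTDS,
    scheme_names: Sequence[str] = _DISCRETE_SCHEME_NAMES,
) -> pd.DataFrame:
    """Optimal-dose enumeration under the MTD-relative interval.

    One row per true MTD; per scheme, the percentage (count) of doses
    strictly inside (gamma(1-delta), gamma(1+delta)).
    """
    rows = []
    for mtd in mtds:
        iv = optimal_mtd_interval(mtd, delta)
        row: dict[str, object] = {
            "true_mtd": mtd,
            "interval_lower": iv.lower,
            "interval_upper": iv.upper,
        }
        for name in scheme_names:
            count, pct = count_optimal_doses(STUDY_SCHEMES[name], iv)
            row[f"{_SCHEME_LABELS[name]}_pct"] = pct
            row[f"{_SCHEME_LABELS[name]}_count"] = count
        rows.append(row)
    return pd.DataFrame(rows)


def optimal_toxicity_table(
    band: float = DEFAULT_TOX_BAND,
    shapes: Sequence[tuple[str, float]] = STUDY_SHAPES,
    mtds: Sequence[float] = STUDY_MTDS,
    scheme_names: Sequence[str] = _DISCRETE_SCHEME_NAMES,
    space: ModelSpace = ModelSpace(),
    rho0_true_by_shape: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Optimal-dose enumeration under the toxicity-band interval.

    One row per (truth shape, true MTD); per scheme, the percentage
    (count) of doses whose true toxicity lies strictly inside
    (theta - band, theta + band).
    """
    rows = []
    for shape, slant in shapes:
        for mtd in mtds:
            rho0 = _lookup_rho0(shape, slant, dict(rho0_true_by_shape or {}))
            truth = calibrate_truth(shape, rho0, mtd, space, slant=slant)
            iv = optimal_toxicity_interval(truth, band)
            label = shape if not slant else f"{shape}({slant:+g})"
            row: dict[str, object] = {
                "true_distribution": label,
                "true_mtd": mtd,
                "interval_lower": iv.lower,
                "interval_upper": iv.upper,
            }
            for name in scheme_names:
                count, pct = count_optimal_doses(STUDY_SCHEMES[name], iv)
                row[f"{_SCHEME_LABELS[name]}_pct"] = pct
                row[f"{_SCHEME_LABELS[name]}_count"] = count
            rows.append(row)
    return pd.DataFrame(rows)
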