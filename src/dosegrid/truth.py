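"""True dose-toxicity curves and DLT sampling for the simulation study.

A truth curve is a monotone map from standardized dose x in [0, 1] to
DLT probability, of the form p(x) = G(a + b * x) with G the CDF of a
standardized location-scale family: logistic, normal, or skew-normal
with slant parameter lambda.  The intercept a and slope b > 0 are
calibrated so that

    p(x_min) = rho0_true        (DLT probability at the lowest dose)
    p(gamma_true) = theta       (the true MTD hits the target level)

Because the calibration pins two points of an affine transform, any
location/scale choice for the family is absorbed into (a, b): curves
labelled with different (mu, sigma^2) but the same shape are pointwise
identical after calibration.  Only the shape (and slant) matters.

The study grid enumerates 4 truth shapes x 4 true MTDs x 3 sample
sizes x 6 dose schemes per design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit, ndtr, ndtri, owens_t

from .model import ModelSpace

__all__ = [
    "TruthCurve",
    "ScenarioSpec",
    "standardized_cdf",
    "standardized_quantile",
    "calibrate_truth",
    "true_tox_prob",
    "sample_dlt",
    "study_grid",
    "STUDY_SHAPES",
    "DEFAULT_RHO0_TRUE",
    "default_rho0_true",
    "STUDY_MTDS",
    "STUDY_SAMPLE_SIZES",
    "STUDY_SCHEME_NAMES",
]

SHAPES = ("logistic", "normal", "skew_normal")

# The four truth distributions of the study: (shape, slant).
STUDY_SHAPES: tuple[tuple[str, float], ...] = (
    ("logistic", 0.0),
    ("normal", 0.0),
    ("skew_normal", 3.0),
    ("skew_normal", -3.0),
)

STUDY_MTDS = (0.2, 0.4, 0.6, 0.8)
STUDY_SAMPLE_SIZES = (20, 40, 60)
STUDY_SCHEME_NAMES = ("continuous", "d0.05", "d0.10", "d0.125", "d0.20", "d0.25")

# DLT probability at dose 0 for each truth shape.  Not a property of the
# designs: a scenario input.  These values are calibrated so that the
# optimal-toxicity-dose enumeration over the five discrete schemes is
# reproduced exactly for every shape (see docs/methods.md).
DEFAULT_RHO0_TRUE: dict[tuple[str, float], float] = {
    ("logistic", 0.0): 0.10,
    ("normal", 0.0): 0.05,
    ("skew_normal", 3.0): 0.15,
    ("skew_normal", -3.0): 0.01,
}


def default_rho0_true(shape: str, slant: float = 0.0) -> float:
    """Default true DLT probability at dose 0 for a truth shape."""
    try:
        return DEFAULT_RHO0_TRUE[(shape, float(slant))]
    except KeyError:
        raise ValueError(
            f"no default rho0_true for shape {shape!r} with slant {slant}; "
            "pass rho0_true explicitly"
        ) from None


def standardized_cdf(shape: str, u, slant: float = 0.0):
    """CDF of the standardized family at u.

    skew-normal: Phi(u) - 2 * T(u, slant) with T Owen's T function.
    """
    if shape == "logistic":
        return expit(u)
    if shape == "normal":
        return ndtr(u)
    if shape == "skew_normal":
        return ndtr(u) - 2.0 * owens_t(u, slant)
    raise ValueError(f"unknown shape {shape!r}")


def standardized_quantile(shape: str, p: float, slant: float = 0.0) -> float:
    """Inverse CDF of the standardized family.

    Closed form for logistic/normal; monotone bracketing root-find on
    the CDF (to ~1e-12) for the skew-normal.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie in (0, 1), got {p}")
    if shape == "logistic":
        return float(logit(p))
    if shape == "normal":
        return float(ndtri(p))
    if shape == "skew_normal":
        lo, hi = -40.0, 40.0
        return float(
            brentq(lambda u: standardized_cdf(shape, u, slant) - p, lo, hi, xtol=1e-12)
        )
    raise ValueError(f"unknown shape {shape!r}")


@dataclass(frozen=True)
class TruthCurve:
    """Calibrated true dose-toxicity curve p(x) = G(intercept + slope * x)."""

    shape: str
    slant: float
    rho0_true: float
    gamma_true: float
    theta: float
    intercept: float
    slope: float
    x_min: float = 0.0
    x_max: float = 1.0

    def prob(self, x):
        """True DLT probability at dose x."""
        return standardized_cdf(self.shape, self.intercept + self.slope * np.asarray(x), self.slant)

    def inverse_prob(self, p: float) -> float:
        """Dose at which the true toxicity equals p (unclipped)."""
        return (standardized_quantile(self.shape, p, self.slant) - self.intercept) / self.slope


def calibrate_truth(
    shape: str,
    rho0_true: float,
    gamma_true: float,
    space: ModelSpace = ModelSpace(),
    slant: float = 0.0,
) -> TruthCurve:
    """Solve the intercept/slope anchoring p(x_min) = rho0_true, p(gamma_true) = theta."""
    if not 0.0 < rho0_true < space.theta:
        raise ValueError(
            f"rho0_true must lie in (0, theta) = (0, {space.theta}), got {rho0_true}"
        )
    if not space.x_min < gamma_true <= space.x_max:
        raise ValueError(
            f"gamma_true must lie in ({space.x_min}, {space.x_max}], got {gamma_true}"
        )
    q_lo = standardized_quantile(shape, rho0_true, slant)
    q_mtd = standardized_quantile(shape, space.theta, slant)
    slope = (q_mtd - q_lo) / (gamma_true - space.x_min)
    intercept = q_lo - slope * space.x_min
    return TruthCurve(
        shape=shape,
        slant=slant,
        rho0_true=rho0_true,
        gamma_true=gamma_true,
        theta=space.theta,
        intercept=float(intercept),
        slope=float(slope),
        x_min=space.x_min,
        x_max=space.x_max,
    )


def true_tox_prob(curve: TruthCurve, x):
    """True DLT probability at dose x (must lie in the dose interval)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < curve.x_min) or np.any(x > curve.x_max):
        raise ValueError("dose outside the standardized interval")
    return curve.prob(x)


def sample_dlt(curve: TruthCurve, x: float, rng: np.random.Generator) -> int:
    """Bernoulli DLT outcome at dose x from the truth curve."""
    return int(rng.random() < true_tox_prob(curve, x))


def _lookup_rho0(shape: str, slant: float, overrides: dict | None) -> float:
    if overrides:
        if (shape, float(slant)) in overrides:
            return float(overrides[(shape, float(slant))])
        if shape in overrides:
            return float(overrides[shape])
    return default_rho0_true(shape, slant)


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the simulation study."""

    shape: str
    slant: float
    rho0_true: float
    gamma_true: float
    n: int
    design: str
    scheme_name: str
    replicates: int
    seed: int
    index: int

    @property
    def scenario_id(self) -> str:
        slant = f"{self.slant:+g}" if self.slant else ""
        return (
            f"{self.design}|{self.shape}{slant}|mtd{self.gamma_true:g}"
            f"|n{self.n}|{self.scheme_name}"
        )

    def truth(self, space: ModelSpace = ModelSpace()) -> TruthCurve:
        return calibrate_truth(
            self.shape, self.rho0_true, self.gamma_true, space, slant=self.slant
        )


def study_grid(
    designs: Sequence[str] = ("crm", "ewoc"),
    shapes: Sequence[tuple[str, float]] = STUDY_SHAPES,
    mtds: Sequence[float] = STUDY_MTDS,
    sample_sizes: Sequence[int] = STUDY_SAMPLE_SIZES,
    scheme_names: Sequence[str] = STUDY_SCHEME_NAMES,
    replicates: int = 1000,
    base_seed: int = 0,
    rho0_true_by_shape: dict | None = None,
) -> list[ScenarioSpec]:
    """Enumerate the full scenario grid with distinct per-scenario seeds.

    The default grid is 4 shapes x 4 MTDs x 3 sample sizes x 6 schemes
    per design (288 scenarios per design).  ``rho0_true_by_shape``
    overrides the per-shape rho0 defaults; keys are (shape, slant)
    pairs or bare shape names.
    """
    specs: list[ScenarioSpec] = []
    idx = 0
    for design in designs:
        for shape, slant in shapes:
            for mtd in mtds:
                for n in sample_sizes:
                    for scheme_name in scheme_names:
                        seed = int(
                            np.random.SeedSequence([base_seed, idx]).generate_state(1)[0]
                        )
                        specs.append(
                            ScenarioSpec(
                                shape=shape,
                                slant=slant,
                                rho0_true=_lookup_rho0(
                                    shape, slant, rho0_true_by_shape
                                ),
                                gamma_true=mtd,
                                n=n,
                                design=design,
                                scheme_name=scheme_name,
                                replicates=replicates,
                                seed=seed,
                                index=idx,
                            )
                        )
                        idx += 1
    return specs
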