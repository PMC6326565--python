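"""Bayesian working model for phase I dose-finding.

The dose-toxicity relationship is a two-parameter logistic model

    P(DLT | dose = x) = F(beta0 + beta1 * x),    F(u) = 1 / (1 + exp(-u)),

reparametrized in terms of the two quantities a clinician can reason
about directly:

* ``rho0`` -- the probability of a dose-limiting toxicity (DLT) at the
  minimum dose ``x_min``, and
* ``gamma`` -- the maximum tolerated dose (MTD), i.e. the dose at which
  the DLT probability equals the target toxicity level ``theta``.

The mapping between the two parametrizations is

    beta0 = (gamma * F^-1(rho0) - x_min * F^-1(theta)) / (gamma - x_min)
    beta1 = (F^-1(theta) - F^-1(rho0)) / (gamma - x_min)

which requires ``rho0 < theta`` so that ``beta1 > 0`` (monotone
increasing toxicity).

The posterior over ``(rho0, gamma)`` is computed by deterministic
tensor-grid quadrature over the bounded parameter box (midpoint rule on
both axes, log-space accumulation).  This makes every posterior summary
exactly reproducible: there is no Monte Carlo error in the dose
recommendations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit, logit
from scipy.stats import beta as beta_dist

__all__ = [
    "ModelSpace",
    "ModelParams",
    "CanonicalCoefficients",
    "TrialHistory",
    "PriorSpec",
    "PosteriorGrid",
    "link_cdf",
    "link_quantile",
    "canonical_from_reparam",
    "log_likelihood",
    "posterior_update",
    "gamma_posterior_mean",
    "rho0_posterior_mean",
    "gamma_posterior_quantile",
]

DEFAULT_RESOLUTION = (201, 201)


@dataclass(frozen=True)
class ModelSpace:
    """Standardized dose interval and target toxicity level.

    Doses are standardized so that ``x_min`` and ``x_max`` are the lowest
    and highest administrable doses; ``theta`` is the acceptable DLT
    probability at the MTD (0.33 throughout the study).
    """

    x_min: float = 0.0
    x_max: float = 1.0
    theta: float = 0.33

    def __post_init__(self) -> None:
        if not self.x_min < self.x_max:
            raise ValueError(f"x_min must be < x_max, got [{self.x_min}, {self.x_max}]")
        if not 0.0 < self.theta < 1.0:
            raise ValueError(f"theta must lie in (0, 1), got {self.theta}")


@dataclass(frozen=True)
class ModelParams:
    """Model parameters on the clinical scale: (rho0, gamma)."""

    rho0: float
    gamma: float

    def validate(self, space: ModelSpace) -> None:
        if not 0.0 < self.rho0 < space.theta:
            raise ValueError(
                f"rho0 must lie in (0, theta) = (0, {space.theta}) for beta1 > 0, got {self.rho0}"
            )
        if not space.x_min <= self.gamma <= space.x_max:
            raise ValueError(
                f"gamma must lie in [{space.x_min}, {space.x_max}], got {self.gamma}"
            )


@dataclass(frozen=True)
class CanonicalCoefficients:
    """Intercept and slope on the link scale; beta1 > 0 by construction."""

    beta0: float
    beta1: float


class TrialHistory:
    """Ordered (dose, DLT) records accumulated during one trial."""

    def __init__(self, records: Iterable[tuple[float, int]] = ()) -> None:
        self.records: list[tuple[float, int]] = []
        for dose, dlt in records:
            self.append(dose, dlt)

    def append(self, dose: float, dlt: int) -> None:
        if dlt not in (0, 1):
            raise ValueError(f"dlt must be 0 or 1, got {dlt}")
        self.records.append((float(dose), int(dlt)))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def doses(self) -> np.ndarray:
        return np.array([r[0] for r in self.records], dtype=float)

    @property
    def dlts(self) -> np.ndarray:
        return np.array([r[1] for r in self.records], dtype=int)

    def validate(self, space: ModelSpace) -> None:
        for dose, _ in self.records:
            if not space.x_min <= dose <= space.x_max:
                raise ValueError(f"dose {dose} outside [{space.x_min}, {space.x_max}]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_index": np.arange(1, len(self) + 1),
                "dose": self.doses,
                "dlt": self.dlts,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialHistory":
        df = pd.read_csv(path).sort_values("patient_index")
        return cls(zip(df["dose"], df["dlt"]))

    def __repr__(self) -> str:  # pragma: no cover
        return f"TrialHistory({self.records!r})"


@dataclass(frozen=True)
class PriorSpec:
    """Prior over (rho0, gamma) on the bounded box.

    ``uniform`` (the study default) is flat over rho0 in (0, 1) and
    gamma in [x_min, x_max].  ``beta`` uses an independent
    Beta(a_rho, b_rho) for rho0 and a rescaled Beta(a_gamma, b_gamma)
    for gamma.  With ``truncate_rho0`` (default), density is zero where
    rho0 >= theta, enforcing a positive slope beta1 > 0.
    """

    family: str = "uniform"
    hyperparams: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    truncate_rho0: bool = True

    def __post_init__(self) -> None:
        if self.family not in ("uniform", "beta"):
            raise ValueError(f"unknown prior family {self.family!r}")

    def log_density(
        self, rho0: np.ndarray, gamma: np.ndarray, space: ModelSpace
    ) -> np.ndarray:
        """Log prior density on a broadcastable (rho0, gamma) mesh."""
        rho0, gamma = np.broadcast_arrays(rho0, gamma)
        if self.family == "uniform":
            out = np.zeros(rho0.shape)
        else:
            a_r, b_r, a_g, b_g = self.hyperparams
            g01 = (gamma - space.x_min) / (space.x_max - space.x_min)
            out = beta_dist.logpdf(rho0, a_r, b_r) + beta_dist.logpdf(g01, a_g, b_g)
        if self.truncate_rho0:
            out = np.where(rho0 >= space.theta, -np.inf, out)
        return out

    def rho0_support_upper(self, space: ModelSpace) -> float:
        return space.theta if self.truncate_rho0 else 1.0


@dataclass
class PosteriorGrid:
    """Discretized joint posterior over (rho0, gamma).

    ``weights`` is a (len(rho0_nodes), len(gamma_nodes)) matrix of
    normalized probability masses; ``gamma_marginal`` its column sums.
    Nodes are midpoints of equal cells, so each weight represents the
    posterior mass of one rectangular cell.
    """

    rho0_nodes: np.ndarray
    gamma_nodes: np.ndarray
    weights: np.ndarray
    gamma_marginal: np.ndarray = field(init=False)
    space: ModelSpace = field(default_factory=ModelSpace)

    def __post_init__(self) -> None:
        total = float(self.weights.sum())
        if not np.isfinite(total) or abs(total - 1.0) > 1e-10:
            raise ValueError(f"weights must sum to 1 within 1e-10, got {total}")
        self.gamma_marginal = self.weights.sum(axis=0)


def link_cdf(u):
    """Standard logistic CDF F(u) = 1 / (1 + exp(-u))."""
    return expit(u)


def link_quantile(p):
    """Inverse of :func:`link_cdf` (the logit)."""
    return logit(p)


def canonical_from_reparam(
    params: ModelParams, space: ModelSpace
) -> CanonicalCoefficients:
    """Map (rho0, gamma) to the link-scale coefficients (beta0, beta1)."""
    params.validate(space)
    if params.gamma <= space.x_min:
        raise ValueError("gamma must exceed x_min (degenerate slope otherwise)")
    span = params.gamma - space.x_min
    q_rho, q_theta = link_quantile(params.rho0), link_quantile(space.theta)
    beta1 = (q_theta - q_rho) / span
    beta0 = (params.gamma * q_rho - space.x_min * q_theta) / span
    return CanonicalCoefficients(beta0=float(beta0), beta1=float(beta1))


def log_likelihood(
    params: ModelParams, history: TrialHistory, space: ModelSpace
) -> float:
    """Bernoulli log-likelihood of the accumulated (dose, DLT) records."""
    if len(history) == 0:
        return 0.0
    coef = canonical_from_reparam(params, space)
    eta = coef.beta0 + coef.beta1 * history.doses
    y = history.dlts
    # log F(eta) = log_expit(eta); log(1 - F(eta)) = log_expit(-eta)
    return float(np.sum(y * log_expit(eta) + (1 - y) * log_expit(-eta)))


def _midpoints(lo: float, hi: float, n: int) -> np.ndarray:
    edges = np.linspace(lo, hi, n + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def _check_resolution(resolution: Sequence[int]) -> tuple[int, int]:
    n_rho, n_gamma = int(resolution[0]), int(resolution[1])
    if n_rho < 64 or n_gamma < 64:
        raise ValueError(f"resolution must be >= 64 nodes per axis, got {resolution}")
    return n_rho, n_gamma


class PosteriorAccumulator:
    """Incremental log-likelihood accumulation on a fixed parameter grid.

    Used by the trial engine so that the posterior after k patients is
    obtained by adding one record's contribution rather than re-scanning
    the history; :func:`posterior_update` goes through the same code
    path, so sequential and batch updating agree bitwise.

    Per-(dose, outcome) grid terms are cached: under a discrete dose
    scheme only a handful of distinct doses ever occur.
    """

    def __init__(
        self,
        prior: PriorSpec,
        space: ModelSpace,
        resolution: Sequence[int] = DEFAULT_RESOLUTION,
    ) -> None:
        n_rho, n_gamma = _check_resolution(resolution)
        self.space = space
        self.prior = prior
        self.rho0_nodes = _midpoints(0.0, prior.rho0_support_upper(space), n_rho)
        self.gamma_nodes = _midpoints(space.x_min, space.x_max, n_gamma)
        rr = self.rho0_nodes[:, None]
        gg = self.gamma_nodes[None, :]
        span = gg - space.x_min
        q_rho = logit(rr)
        q_theta = logit(space.theta)
        with np.errstate(divide="ignore", invalid="ignore"):
            self._beta1 = (q_theta - q_rho) / span
            self._beta0 = (gg * q_rho - space.x_min * q_theta) / span
        self._log_prior = prior.log_density(rr, gg, space)
        self._loglik = np.zeros((n_rho, n_gamma))
        self._cache: dict[tuple[float, int], np.ndarray] = {}

    def _record_term(self, dose: float, dlt: int) -> np.ndarray:
        key = (round(float(dose), 12), int(dlt))
        term = self._cache.get(key)
        if term is None:
            eta = self._beta0 + self._beta1 * dose
            term = log_expit(eta) if dlt == 1 else log_expit(-eta)
            term = np.where(np.isfinite(term), term, -np.inf)
            self._cache[key] = term
        return term

    def add(self, dose: float, dlt: int) -> None:
        self._loglik = self._loglik + self._record_term(dose, dlt)

    def grid(self) -> PosteriorGrid:
        log_post = self._loglik + self._log_prior
        m = np.max(log_post)
        if not np.isfinite(m):
            raise FloatingPointError("posterior has no finite mass on the grid")
        w = np.exp(log_post - m)
        w /= w.sum()
        return PosteriorGrid(
            rho0_nodes=self.rho0_nodes,
            gamma_nodes=self.gamma_nodes,
            weights=w,
            space=self.space,
        )


def posterior_update(
    prior: PriorSpec,
    history: TrialHistory,
    space: ModelSpace,
    resolution: Sequence[int] = DEFAULT_RESOLUTION,
) -> PosteriorGrid:
    """Grid-quadrature posterior over (rho0, gamma) given the history.

    Deterministic for fixed inputs and resolution.  The default
    201 x 201 grid puts rho0 nodes at cell midpoints of (0, theta)
    (or (0, 1) without truncation) and gamma nodes at cell midpoints of
    [x_min, x_max].
    """
    history.validate(space)
    acc = PosteriorAccumulator(prior, space, resolution)
    for dose, dlt in history:
        acc.add(dose, dlt)
    return acc.grid()


def _require_normalized(grid: PosteriorGrid) -> None:
    if abs(float(grid.weights.sum()) - 1.0) > 1e-10:
        raise ValueError("posterior grid is not normalized")


def gamma_posterior_mean(grid: PosteriorGrid) -> float:
    """Posterior mean of the MTD gamma."""
    _require_normalized(grid)
    return float(np.dot(grid.gamma_marginal, grid.gamma_nodes))


def rho0_posterior_mean(grid: PosteriorGrid) -> float:
    """Posterior mean of rho0, the DLT probability at the minimum dose."""
    _require_normalized(grid)
    return float(np.dot(grid.weights.sum(axis=1), grid.rho0_nodes))


def gamma_posterior_quantile(grid: PosteriorGrid, alpha: float) -> float:
    """alpha-quantile of the gamma marginal.

    Linear interpolation on the midpoint CDF: the cumulative mass at a
    node is taken as (mass strictly left) + half the node's own mass,
    anchored at (x_min, 0) and (x_max, 1).  For the k = 0 uniform prior
    this returns exact uniform quantiles.  Ties resolve to the leftmost
    attaining dose.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    _require_normalized(grid)
    w = grid.gamma_marginal
    cdf_mid = np.cumsum(w) - 0.5 * w
    xs = np.concatenate(([grid.space.x_min], grid.gamma_nodes, [grid.space.x_max]))
    cs = np.concatenate(([0.0], cdf_mid, [1.0]))
    # np.interp picks the leftmost x where the CDF is flat at alpha
    return float(np.interp(alpha, cs, xs))
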