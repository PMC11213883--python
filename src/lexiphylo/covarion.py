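"""Binary covarion substitution process, relaxed lognormal clock, and priors.

The covarion process has four states, ordered

    0 = absent/slow, 1 = present/slow, 2 = absent/fast, 3 = present/fast.

Within the slow category, gain/loss happens at a fraction ``alpha`` of the
fast-category rate; the hidden category toggles at rate ``s`` without a
simultaneous change of the observed state.  Hidden-state frequencies default
to (0.5, 0.5) and the observed equilibrium frequencies (f_absent, f_present)
are typically set to their empirical values in the data.

The generator is normalized so that the expected *observed-state* change
rate at stationarity is 1: clock rates are then interpretable as expected
cognate gains+losses per year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trees import TimeTree

__all__ = [
    "CovarionParams", "ClockModel", "PriorConfig",
    "rate_matrix", "stationary_distribution", "transition_probabilities",
    "TransitionMatrixCache", "log_prior", "conditioned_yule_log_density",
]

N_STATES = 4
OBSERVED_ABSENT = (0, 2)
OBSERVED_PRESENT = (1, 3)


@dataclass(frozen=True)
class CovarionParams:
    """Parameters of the 4-state binary covarion process.

    alpha : slow-category rate fraction, in (0, 1]
    s     : hidden-category switch rate, > 0
    f_absent, f_present : observed-state equilibrium frequencies, sum to 1
    hidden_freqs : hidden-category frequencies, sum to 1 (default 0.5/0.5)
    """

    alpha: float = 0.5
    s: float = 0.5
    f_absent: float = 0.992
    f_present: float = 0.008
    hidden_freqs: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not self.s > 0:
            raise ValueError(f"switch rate must be positive, got {self.s}")
        if not (self.f_absent > 0 and self.f_present > 0):
            raise ValueError("state frequencies must be positive")
        if abs(self.f_absent + self.f_present - 1.0) > 1e-9:
            raise ValueError("f_absent + f_present must equal 1")
        if abs(sum(self.hidden_freqs) - 1.0) > 1e-9:
            raise ValueError("hidden frequencies must sum to 1")


@dataclass
class ClockModel:
    """Lognormal relaxed clock.

    mean_rate : expected substitutions per cognate per year
    stdev     : standard deviation (log space) of branch-rate multipliers
    Branch rate multipliers themselves live on the tree nodes; their prior
    is lognormal with unit mean (meanlog = -stdev^2/2, sdlog = stdev).
    """

    mean_rate: float = math.exp(-10.0)
    stdev: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_rate <= 0:
            raise ValueError("clock mean rate must be positive")
        if self.stdev < 0:
            raise ValueError("clock stdev must be non-negative")


@dataclass
class PriorConfig:
    """Hyperpriors of the analysis.

    Lognormal priors are parameterized by (meanlog, sdlog) of the underlying
    normal in natural-log space; the gamma prior by (shape, scale).  The
    root-age calibration is a normal on years BP.
    """

    birth_rate_prior: tuple[float, float] = (-7.5, 2.0)
    clock_mean_prior: tuple[float, float] = (-10.0, 2.0)
    clock_stdev_prior: tuple[float, float] = (0.5396, 0.3819)  # shape, scale
    root_age_prior: tuple[float, float] = (5200.0, 100.0)      # mean, sd (years BP)
    # switch-rate prior (meanlog, sdlog); alpha is uniform on (0, 1]
    switch_rate_prior: tuple[float, float] = (-1.0, 1.0)
    gamma_is_shape_rate: bool = False  # alternative reading of the stdev prior

    def __post_init__(self) -> None:
        for name in ("birth_rate_prior", "clock_mean_prior", "clock_stdev_prior",
                     "root_age_prior", "switch_rate_prior"):
            a, b = getattr(self, name)
            if not (math.isfinite(a) and math.isfinite(b)) or b <= 0:
                raise ValueError(f"invalid hyperparameters for {name}: {(a, b)}")


# --------------------------------------------------------------------- matrix

def rate_matrix(params: CovarionParams, normalized: bool = True) -> np.ndarray:
    """Instantaneous 4x4 rate matrix Q of the covarion process.

    Rows sum to zero.  When ``normalized`` the matrix is rescaled so the
    expected observed-state change rate at stationarity equals 1.
    """
    a, s = params.alpha, params.s
    f0, f1 = params.f_absent, params.f_present
    h0, h1 = params.hidden_freqs
    Q = np.zeros((4, 4))
    Q[0, 1] = a * f1
    Q[1, 0] = a * f0
    Q[2, 3] = f1
    Q[3, 2] = f0
    # hidden switching: 2*s*h equals s at the default (0.5, 0.5) hidden
    # frequencies and keeps the process reversible if they are overridden
    Q[0, 2] = Q[1, 3] = 2.0 * s * h1
    Q[2, 0] = Q[3, 1] = 2.0 * s * h0
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if normalized:
        # E[observed change rate] = sum_i pi_i * (rate of observed change from i)
        h0, h1 = params.hidden_freqs
        mu = h0 * (f0 * a * f1 + f1 * a * f0) + h1 * (f0 * f1 + f1 * f0)
        Q = Q / mu
    return Q


def stationary_distribution(params: CovarionParams) -> np.ndarray:
    h0, h1 = params.hidden_freqs
    return np.array([h0 * params.f_absent, h0 * params.f_present,
                     h1 * params.f_absent, h1 * params.f_present])


class TransitionMatrixCache:
    """Eigendecomposition of Q for fast transition probabilities.

    The process is reversible with respect to its stationary distribution, so
    D^{1/2} Q D^{-1/2} is symmetric and a single `eigh` yields P(t) for any
    batch of distances via broadcasting.
    """

    def __init__(self, params: CovarionParams) -> None:
        self.params = params
        Q = rate_matrix(params)
        pi = stationary_distribution(params)
        d = np.sqrt(pi)
        S = (Q * d[:, None]) / d[None, :]
        S = 0.5 * (S + S.T)  # symmetrize away rounding noise
        w, U = np.linalg.eigh(S)
        self.pi = pi
        self._w = w
        self._A = (1.0 / d)[:, None] * U          # D^{-1/2} U
        self._B = U.T * d[None, :]                # U^T D^{1/2}

    def probabilities(self, distances: np.ndarray | float) -> np.ndarray:
        """P(t) for scalar or array of distances; shape (..., 4, 4)."""
        t = np.asarray(distances, dtype=float)
        if np.any(t < 0):
            raise ValueError("distance must be non-negative")
        e = np.exp(t[..., None] * self._w)        # (..., 4)
        P = np.einsum("ik,...k,kj->...ij", self._A, e, self._B)
        np.clip(P, 0.0, None, out=P)
        return P


def transition_probabilities(params: CovarionParams, distance: float) -> np.ndarray:
    """4x4 stochastic matrix exp(Q * distance)."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return TransitionMatrixCache(params).probabilities(float(distance))


# --------------------------------------------------------------------- priors

def _lognormal_logpdf(x: float, meanlog: float, sdlog: float) -> float:
    if x <= 0:
        return -math.inf
    z = (math.log(x) - meanlog) / sdlog
    return -math.log(x * sdlog * math.sqrt(2 * math.pi)) - 0.5 * z * z


def _normal_logpdf(x: float, mean: float, sd: float) -> float:
    z = (x - mean) / sd
    return -math.log(sd * math.sqrt(2 * math.pi)) - 0.5 * z * z


def _gamma_logpdf(x: float, shape: float, scale: float) -> float:
    if x <= 0:
        return -math.inf
    return ((shape - 1.0) * math.log(x) - x / scale
            - math.lgamma(shape) - shape * math.log(scale))


def conditioned_yule_log_density(tree: TimeTree, birth_rate: float) -> float:
    """Log density of interior node ages under the root-conditioned Yule prior.

    Conditional on the root age T and the number of tips n, the n-2
    non-root interior node ages are iid with density
    lam * exp(-lam * a) / (1 - exp(-lam * T)) on (0, T); the topology is
    uniform over labeled histories (a constant, omitted).
    """
    if birth_rate <= 0:
        return -math.inf
    lam = birth_rate
    T = tree.root.age
    if T <= 0:
        return -math.inf
    lognorm = math.log1p(-math.exp(-lam * T))
    total = 0.0
    for node in tree.internal_nodes:
        if node is tree.root:
            continue
        a = node.age
        if not (0.0 < a < T):
            return -math.inf
        total += math.log(lam) - lam * a - lognorm
    return total


def log_prior(tree: TimeTree, clock: ClockModel, params: CovarionParams,
              priors: PriorConfig, birth_rate: float) -> float:
    """Joint log prior of (tree, clock, covarion parameters, birth rate).

    Sum of the conditioned-Yule node-age density, the root-age calibration,
    the birth-rate / clock-mean lognormal and clock-stdev gamma hyperpriors,
    the per-branch lognormal rate densities, and the covarion parameter
    priors (alpha uniform on (0,1], switch rate lognormal).

    A strict clock (stdev == 0) contributes 0 for the branch-rate term by
    convention (point mass at rate 1); branch rates then must all be 1.
    """
    for node in tree.internal_nodes:
        if len(node.children) != 2:
            raise ValueError("tree must be binary for the Yule prior")

    lp = conditioned_yule_log_density(tree, birth_rate)
    lp += _normal_logpdf(tree.root.age, *priors.root_age_prior)
    lp += _lognormal_logpdf(birth_rate, *priors.birth_rate_prior)
    lp += _lognormal_logpdf(clock.mean_rate, *priors.clock_mean_prior)
    shape, second = priors.clock_stdev_prior
    scale = 1.0 / second if priors.gamma_is_shape_rate else second
    if clock.stdev > 0:
        lp += _gamma_logpdf(clock.stdev, shape, scale)
        meanlog = -0.5 * clock.stdev ** 2
        for node in tree.postorder():
            if node.parent is None:
                continue
            lp += _lognormal_logpdf(node.rate, meanlog, clock.stdev)
    else:
        for node in tree.postorder():
            if node.parent is not None and abs(node.rate - 1.0) > 1e-12:
                return -math.inf
    # covarion parameters
    if not (0.0 < params.alpha <= 1.0):
        return -math.inf
    lp += _lognormal_logpdf(params.s, *priors.switch_rate_prior)
    return lp
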