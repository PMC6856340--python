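"""Invariant Density Analysis (IDA) of postural sway.

The displacement of the centre of pressure from its centroid is discretized
into a finite number of distance states and modelled as a first-order Markov
chain.  With a small additive regularization the chain is irreducible and
aperiodic, so its distribution converges to a unique stationary (invariant)
density pi.  Five scalar summaries of pi and of the transition matrix P are
computed:

* ``P_peak`` -- the peak value of pi;
* ``D_bar`` -- mean COP distance from the centroid under pi (mm);
* ``D95``   -- smallest state (bin centre, mm) by which the cumulative
  invariant density reaches 95%;
* ``lambda2`` -- modulus of the second-largest eigenvalue of P, the rate of
  convergence to pi;
* ``H`` -- Shannon entropy of pi in bits, ``H = -sum_i pi(i) log2 pi(i)``,
  the randomness of the long-run sway distribution.

In addition the first zero crossing ``z_lambda2`` of the left eigenvector
belonging to lambda2 is located.  The sign structure of that eigenvector
splits the state space into two sets with distinct dynamics; the crossing is
interpreted as the boundary between a freely-diffusing region near the
centroid and an actively-controlled region farther out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .errors import DataError, NumericalError, ParameterError
from .signal import DirectionalSeries

__all__ = [
    "BinGeometry",
    "MarkovModel",
    "IdaResult",
    "make_bins",
    "state_values",
    "discretize",
    "estimate_transition_matrix",
    "stationary_density",
    "entropy",
    "ida_summary",
    "second_eigenvector_zero_crossing",
]

#: Default number of distance states.
DEFAULT_N_STATES = 60
#: Default transition lag in samples (at the 100 Hz analysis rate).
DEFAULT_LAG = 1
#: Default additive pseudomass applied to every transition cell.
DEFAULT_EPSILON = 1e-8


@dataclass(frozen=True)
class BinGeometry:
    """Uniform half-open distance bins [edges[i], edges[i+1]) on [0, max].

    The last bin is closed so the pooled maximum falls inside the state
    space.  Bin centres are the midpoints of the edges.
    """

    edges: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        if len(edges) < 3:
            raise ParameterError("need at least 2 states (3 edges)")
        if edges[0] != 0.0:
            raise ParameterError("first edge must be 0")
        if np.any(np.diff(edges) <= 0):
            raise ParameterError("edges must be strictly increasing")
        object.__setattr__(self, "edges", edges)

    @property
    def n_states(self) -> int:
        return len(self.edges) - 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def width(self) -> np.ndarray:
        return np.diff(self.edges)


@dataclass(frozen=True)
class MarkovModel:
    """Discretized state sequence with its regularized transition matrix."""

    states: np.ndarray
    P: np.ndarray
    lag: int = DEFAULT_LAG
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ParameterError("P must be square")
        if np.any(P <= 0):
            raise ParameterError("P must be strictly positive after regularization")
        if np.max(np.abs(P.sum(axis=1) - 1.0)) > 1e-12:
            raise ParameterError("rows of P must sum to 1 within 1e-12")
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "states", np.asarray(self.states, dtype=np.intp))

    @property
    def n_states(self) -> int:
        return self.P.shape[0]


@dataclass(frozen=True)
class IdaResult:
    """IDA summary for one directional series."""

    pi: np.ndarray
    P_peak: float
    D_bar: float
    D95: float
    lambda2: float
    H: float
    z_lambda2: float = field(default=np.nan)

    def as_dict(self) -> dict[str, float]:
        return {
            "P_peak": self.P_peak,
            "D_bar_mm": self.D_bar,
            "D95_mm": self.D95,
            "lambda2": self.lambda2,
            "H_bits": self.H,
            "z_lambda2_mm": self.z_lambda2,
        }


def state_values(series: DirectionalSeries) -> np.ndarray:
    """Distance-from-centroid values used as the IDA state variable.

    Signed AP/ML series are folded to their absolute displacement; the
    radial series is already a distance.
    """
    x = np.asarray(series.x, dtype=float)
    return x if series.direction == "Rad" else np.abs(x)


def make_bins(
    series_pool: DirectionalSeries | list[DirectionalSeries],
    n_states: int = DEFAULT_N_STATES,
) -> BinGeometry:
    """Build a shared bin geometry spanning [0, pooled max displacement].

    All trials that will be compared must be discretized on the same
    geometry, otherwise their entropies live on different state spaces.
    """
    if isinstance(series_pool, DirectionalSeries):
        series_pool = [series_pool]
    if n_states < 2:
        raise ParameterError("n_states must be >= 2 (entropy degenerate otherwise)")
    if not series_pool:
        raise DataError("empty series pool")
    vmax = max(float(np.max(state_values(s))) for s in series_pool)
    if vmax <= 0:
        raise DataError("all-zero pool: cannot build a bin geometry")
    return BinGeometry(edges=np.linspace(0.0, vmax, n_states + 1))


def discretize(series: DirectionalSeries, bins: BinGeometry) -> np.ndarray:
    """Map a directional series onto integer states in [0, n_states).

    Bins are half-open with the last bin closed; a value exactly on an
    interior edge goes to the upper bin.  Values beyond the last edge are
    clipped into the last bin with a warning.
    """
    v = state_values(series)
    if len(v) == 0:
        raise DataError("empty series")
    beyond = v > bins.edges[-1]
    if np.any(beyond):
        warnings.warn(
            f"{int(beyond.sum())} value(s) beyond the last bin edge "
            f"({bins.edges[-1]:.6g} mm); clipped to the last bin",
            stacklevel=2,
        )
    idx = np.searchsorted(bins.edges, v, side="right") - 1
    return np.clip(idx, 0, bins.n_states - 1)


def estimate_transition_matrix(
    states: np.ndarray,
    bins: BinGeometry,
    lag: int = DEFAULT_LAG,
    epsilon: float = DEFAULT_EPSILON,
) -> MarkovModel:
    """Count lagged transitions and regularize into a row-stochastic matrix.

    ``P[i, j]`` is proportional to the number of observed i -> j transitions
    at the given lag plus ``epsilon``.  The pseudomass makes every entry
    strictly positive, hence the chain irreducible and aperiodic with a
    unique stationary density.
    """
    states = np.asarray(states, dtype=np.intp)
    if len(states) == 0:
        raise DataError("empty state sequence")
    if lag < 1:
        raise ParameterError("lag must be >= 1 sample")
    if len(states) <= lag:
        raise DataError(f"sequence of length {len(states)} too short for lag {lag}")
    if epsilon <= 0:
        raise ParameterError("epsilon must be > 0")
    n = bins.n_states
    counts = np.zeros((n, n))
    np.add.at(counts, (states[:-lag], states[lag:]), 1.0)
    # A state whose only observed transitions are self-transitions can only
    # be the trial's final dwell, which is right-censored (its exit was never
    # observed).  Left as is, tiny regularization would make it almost
    # absorbing and collapse the stationary density onto it; censoring the
    # unexited dwell keeps the chain honest about what was observed.
    off_diag = counts.sum(axis=1) - np.diag(counts)
    censored = (np.diag(counts) > 0) & (off_diag == 0)
    counts[censored, censored] = 0.0
    counts += epsilon
    P = counts / counts.sum(axis=1, keepdims=True)
    return MarkovModel(states=states, P=P, lag=lag, epsilon=epsilon)


def transition_counts(states: np.ndarray, n_states: int, lag: int = 1) -> np.ndarray:
    """Raw (un-regularized) lagged transition count matrix."""
    states = np.asarray(states, dtype=np.intp)
    counts = np.zeros((n_states, n_states))
    np.add.at(counts, (states[:-lag], states[lag:]), 1.0)
    return counts


def _power_iteration_pi(
    P: np.ndarray, tol: float = 1e-13, max_iter: int = 200_000
) -> np.ndarray:
    """Stationary density by repeated left-multiplication (reference route)."""
    n = P.shape[0]
    v = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        v_next = v @ P
        v_next /= v_next.sum()
        if np.max(np.abs(v_next - v)) < tol:
            return v_next
        v = v_next
    return v


def stationary_density(
    model: MarkovModel | np.ndarray,
    cross_check: bool = True,
    check_tol: float = 1e-8,
) -> np.ndarray:
    """Invariant density pi of a regularized chain: pi P = pi, sum pi = 1.

    Computed from the eigen-decomposition of ``P.T`` (eigenvalue closest
    to 1) and, by default, cross-checked against power iteration; a
    disagreement beyond ``check_tol`` raises :class:`NumericalError`.
    """
    P = model.P if isinstance(model, MarkovModel) else np.asarray(model, dtype=float)
    w, vec = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    if abs(w[k] - 1.0) > 1e-8:
        raise NumericalError(f"no eigenvalue near 1 (closest {w[k]:.6g})")
    pi = np.real(vec[:, k])
    pi = np.abs(pi)
    pi /= pi.sum()
    if cross_check:
        pi_ref = _power_iteration_pi(P)
        if np.max(np.abs(pi - pi_ref)) > check_tol:
            raise NumericalError(
                "eigenvector and power-iteration stationary densities disagree "
                f"by {np.max(np.abs(pi - pi_ref)):.3g} (> {check_tol:g})"
            )
    return pi


def entropy(pi: np.ndarray) -> float:
    """Shannon entropy of a probability vector in bits, with 0 log 0 := 0."""
    pi = np.asarray(pi, dtype=float)
    if np.any(pi < 0):
        raise ParameterError("probabilities must be nonnegative")
    if abs(pi.sum() - 1.0) > 1e-6:
        raise ParameterError(f"probabilities must sum to 1 (got {pi.sum():.6g})")
    nz = pi[pi > 0]
    return float(-np.sum(nz * np.log2(nz)))


def _sorted_eigenvalues(P: np.ndarray) -> np.ndarray:
    """Eigenvalues sorted by decreasing modulus, ties broken by real part."""
    w = np.linalg.eigvals(P)
    order = np.lexsort((-np.real(w), -np.abs(w)))
    return w[order]


def second_eigenvalue(P: np.ndarray) -> complex:
    """Second-largest eigenvalue of P by modulus."""
    return _sorted_eigenvalues(P)[1]


def second_left_eigenvector(P: np.ndarray) -> tuple[complex, np.ndarray]:
    """Left eigenvector of P for the second-largest eigenvalue.

    Left eigenvectors for eigenvalues other than 1 are orthogonal to the
    all-ones right eigenvector, so their components sum to zero.  The sign
    is fixed so the first appreciable component is positive.
    """
    lam2 = second_eigenvalue(P)
    w, vec = linalg.eig(P.T)
    k = int(np.argmin(np.abs(w - lam2)))
    v = vec[:, k]
    if abs(np.imag(lam2)) > 1e-12 * max(1.0, abs(lam2)):
        warnings.warn(
            f"second eigenvalue is complex ({lam2:.6g}); using the real part "
            "of its eigenvector",
            stacklevel=2,
        )
    v = np.real(v)
    nz = np.flatnonzero(np.abs(v) > 1e-12 * np.max(np.abs(v)))
    if len(nz) and v[nz[0]] < 0:
        v = -v
    return lam2, v


def second_eigenvector_zero_crossing(
    model: MarkovModel, bins: BinGeometry
) -> float:
    """Displacement (mm) of the first sign change of the second left eigenvector.

    Scanning from the innermost state outward, the crossing is linearly
    interpolated between the adjacent bin centres.  Returns NaN (with a
    warning) if the eigenvector never changes sign.
    """
    _, v = second_left_eigenvector(model.P)
    centers = bins.centers
    for i in range(len(v) - 1):
        if v[i] == 0.0:
            return float(centers[i])
        if v[i] * v[i + 1] < 0:
            frac = v[i] / (v[i] - v[i + 1])
            return float(centers[i] + frac * (centers[i + 1] - centers[i]))
    warnings.warn("second eigenvector has no sign change", stacklevel=2)
    return float("nan")


def ida_summary(model: MarkovModel, bins: BinGeometry) -> IdaResult:
    """Compute all IDA measures for one fitted Markov model."""
    pi = stationary_density(model)
    centers = bins.centers
    P_peak = float(np.max(pi))
    D_bar = float(np.sum(pi * centers))
    cum = np.cumsum(pi)
    k95 = int(np.argmax(cum >= 0.95 - 1e-12))
    D95 = float(centers[k95])
    lam2 = second_eigenvalue(model.P)
    if abs(np.imag(lam2)) > 1e-12 * max(1.0, abs(lam2)):
        warnings.warn(
            f"second eigenvalue is complex ({lam2:.6g}); reporting its modulus",
            stacklevel=2,
        )
    z = second_eigenvector_zero_crossing(model, bins)
    return IdaResult(
        pi=pi,
        P_peak=P_peak,
        D_bar=D_bar,
        D95=D95,
        lambda2=float(np.abs(lam2)),
        H=entropy(pi),
        z_lambda2=z,
    )


def analyze_series(
    series: DirectionalSeries,
    bins: BinGeometry,
    lag: int = DEFAULT_LAG,
    epsilon: float = DEFAULT_EPSILON,
) -> IdaResult:
    """Discretize, fit the chain and summarize in one call."""
    states = discretize(series, bins)
    model = estimate_transition_matrix(states, bins, lag=lag, epsilon=epsilon)
    return ida_summary(model, bins)
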