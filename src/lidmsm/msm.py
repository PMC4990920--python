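"""Transition counting, transition-matrix estimation and spectral analysis.

The master equation dp/dt = Kp with T = exp(tau K) has the spectral solution

    p(t) = sum_n  (r_n . p(0))  mu_n^(t/tau)  l_n

where mu_n are the eigenvalues of the transition matrix T estimated at lag
tau, and l_n, r_n its biorthonormal left/right eigenvectors.  Each eigenmode
decays with implied timescale tau_n = -tau / ln(mu_n); the stationary mode
(mu_0 = 1, l_0 = pi) is time independent.  A persistent gap between the
slowest and next-slowest implied timescale across lags is the standard
diagnostic for effective two-state kinetics.

Internally matrices are row-stochastic: row i is the distribution over
successors of state i.  The column-stochastic convention (T[j, i] = i -> j
probability), in which the population modes are the *right* eigenvectors, is
the transpose of ours; conversion happens at the I/O boundary and swaps the
left/right eigenvector roles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator

__all__ = [
    "CountMatrix",
    "TransitionModel",
    "PopulationVector",
    "count_transitions",
    "estimate_nonreversible",
    "estimate_reversible_mle",
    "spectral_analysis",
    "implied_timescale_curves",
    "propagate",
    "MarkovStateModel",
]


@dataclass
class CountMatrix:
    """Observed i -> j transition counts at a lag, trimmed to one ergodic set.

    ``ergodic_subset`` maps trimmed state indices back to the original state
    labels; ``dropped_states`` reports what the trimming removed.
    """

    counts: np.ndarray
    lag: int
    n_states: int
    ergodic_subset: list[int]
    dropped_states: list[int] = field(default_factory=list)
    mode: str = "sliding"

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class TransitionModel:
    """Row-stochastic transition matrix with its complete spectral data.

    ``eigenvalues`` are sorted descending (real parts for non-reversible
    estimates; complex pairs are flagged, never silently truncated).
    ``right_eigenvectors``/``left_eigenvectors`` are biorthonormal
    (l_m . r_n = delta_mn); ``stationary`` is the normalized stationary
    distribution; ``implied_timescales[n] = -lag_time / ln(mu_n)``, infinite
    for the stationary mode.  Sign convention for each non-stationary mode:
    the entry sum of the right eigenvector is >= 0, and if that sum vanishes
    the first nonzero entry is positive.
    """

    T: np.ndarray
    lag_time: float
    eigenvalues: np.ndarray | None = None
    right_eigenvectors: np.ndarray | None = None
    left_eigenvectors: np.ndarray | None = None
    stationary: np.ndarray | None = None
    implied_timescales: np.ndarray | None = None
    reversible: bool = False
    complex_modes: list[int] = field(default_factory=list)
    state_labels: list[int] | None = None

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    @property
    def has_spectrum(self) -> bool:
        return self.eigenvalues is not None


@dataclass
class PopulationVector:
    """Probability distribution over states at one time point."""

    p: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p < -1e-12):
            raise ValueError("populations must be nonnegative")
        if abs(self.p.sum() - 1.0) > 1e-10:
            raise ValueError("populations must sum to 1 within 1e-10")


# ---------------------------------------------------------------------------
# counting


def count_transitions(
    label_trajs,
    lag: int,
    mode: str = "sliding",
    n_states: int | None = None,
    trim: bool = True,
) -> CountMatrix:
    """Count state-to-state transitions at a lag and trim to the ergodic core.

    ``sliding`` counts every pair (t, t+lag); ``strided`` counts pairs at
    t = 0, lag, 2 lag, ... only (statistically independent at the model lag).
    Trimming keeps the largest strongly connected component of the count
    graph (most states; ties by total counts) and records the index mapping.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if mode not in ("sliding", "strided"):
        raise ValueError(f"unknown counting mode {mode!r}")
    trajs = [np.asarray(t, dtype=int) for t in label_trajs]
    usable = [t for t in trajs if t.shape[0] > lag]
    if not usable:
        raise ValueError(f"no trajectory is longer than the lag ({lag} frames)")
    if n_states is None:
        n_states = int(max(t.max() for t in usable)) + 1
    counts = np.zeros((n_states, n_states), dtype=np.int64)
    for t in usable:
        if mode == "sliding":
            src, dst = t[:-lag], t[lag:]
        else:
            strided = t[:: lag]
            src, dst = strided[:-1], strided[1:]
        np.add.at(counts, (src, dst), 1)

    if not trim:
        return CountMatrix(counts, lag, n_states, list(range(n_states)), [], mode)

    graph = scipy.sparse.csr_matrix(counts > 0)
    n_comp, membership = connected_components(graph, directed=True, connection="strong")
    sizes = np.bincount(membership, minlength=n_comp)
    best = np.flatnonzero(sizes == sizes.max())
    if best.size > 1:  # tie: keep the component carrying the most counts
        totals = [
            counts[np.ix_(membership == c, membership == c)].sum() for c in best
        ]
        best = [best[int(np.argmax(totals))]]
    keep = np.flatnonzero(membership == best[0])
    dropped = sorted(set(range(n_states)) - set(keep.tolist()))
    trimmed = counts[np.ix_(keep, keep)]
    return CountMatrix(trimmed, lag, len(keep), keep.tolist(), dropped, mode)


# ---------------------------------------------------------------------------
# estimation


def _counts_array(counts) -> tuple[np.ndarray, list[int], int]:
    if isinstance(counts, CountMatrix):
        return np.asarray(counts.counts, dtype=float), counts.ergodic_subset, counts.lag
    arr = np.asarray(counts, dtype=float)
    return arr, list(range(arr.shape[0])), 1


def estimate_nonreversible(counts, lag_time: float | None = None) -> TransitionModel:
    """Multinomial maximum likelihood: T_ij = C_ij / sum_j C_ij."""
    C, labels, lag = _counts_array(counts)
    row_sums = C.sum(axis=1)
    if np.any(row_sums == 0):
        dead = np.flatnonzero(row_sums == 0).tolist()
        raise ValueError(
            f"states {dead} have no outgoing counts after trimming "
            "(internal error: ergodic trimming should have removed them)"
        )
    T = C / row_sums[:, None]
    model = TransitionModel(
        T=T,
        lag_time=float(lag_time) if lag_time is not None else float(lag),
        reversible=False,
        state_labels=labels,
    )
    return spectral_analysis(model)


def estimate_reversible_mle(
    counts, tol: float = 1e-10, max_iter: int = 1_000_000,
    lag_time: float | None = None,
) -> TransitionModel:
    """Reversible maximum-likelihood transition matrix.

    Maximizes prod_ij T_ij^C_ij subject to detailed balance via the standard
    fixed-point iteration on symmetric auxiliary variables:

        x_ij <- (C_ij + C_ji) / (C_i / x_i + C_j / x_j),   T_ij = x_ij / x_i

    where C_i and x_i are row sums.  Detailed balance holds exactly at every
    iterate because x stays symmetric.  Converged when the largest relative
    change of x drops below ``tol``.
    """
    C, labels, lag = _counts_array(counts)
    row_sums = C.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("every state needs at least one outgoing count")
    sym = C + C.T
    support = sym > 0
    x = sym.astype(float).copy()
    for iteration in range(max_iter):
        xi = x.sum(axis=1)
        denom = row_sums / xi
        update = np.zeros_like(x)
        pair_denom = denom[:, None] + denom[None, :]
        update[support] = sym[support] / pair_denom[support]
        delta = np.abs(update - x)
        scale = np.where(x > 0, x, 1.0)
        rel = (delta / scale).max()
        x = update
        if rel < tol:
            break
    else:
        raise RuntimeError(
            f"reversible MLE did not converge in {max_iter} iterations "
            f"(final relative residual {rel:.3e})"
        )
    xi = x.sum(axis=1)
    T = x / xi[:, None]
    pi = xi / xi.sum()
    model = TransitionModel(
        T=T,
        lag_time=float(lag_time) if lag_time is not None else float(lag),
        stationary=pi,
        reversible=True,
        state_labels=labels,
    )
    return spectral_analysis(model)


# ---------------------------------------------------------------------------
# spectra


def _stationary_from_T(T: np.ndarray) -> np.ndarray:
    # minimum-norm solution of pi (T - I) = 0 with sum(pi) = 1; for a
    # degenerate chain (e.g. the identity) this picks the uniform blend
    n = T.shape[0]
    A = np.vstack([T.T - np.eye(n), np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.abs(pi)
    return pi / pi.sum()


def _apply_sign_convention(R: np.ndarray, L: np.ndarray, tol: float = 1e-8):
    for n in range(1, R.shape[1]):
        s = R[:, n].sum()
        if abs(s) <= tol:
            nz = np.flatnonzero(np.abs(R[:, n]) > tol)
            flip = nz.size > 0 and R[nz[0], n] < 0
        else:
            flip = s < 0
        if flip:
            R[:, n] = -R[:, n]
            L[n, :] = -L[n, :]
    return R, L


def spectral_analysis(model_or_T, lag_time: float | None = None,
                      reversible: bool | None = None) -> TransitionModel:
    """Complete the spectral data of a transition matrix.

    For reversible matrices the similarity transform
    D^(1/2) T D^(-1/2) (D = diag(pi)) is symmetric, so a dense symmetric
    eigensolver guarantees a real spectrum and orthogonal modes; left/right
    eigenvectors are recovered as l_n = sqrt(pi) v_n, r_n = v_n / sqrt(pi)
    and are biorthonormal by construction.  Non-reversible matrices go
    through a general eigensolver; complex pairs are recorded in
    ``complex_modes`` and their real parts retained.
    """
    if isinstance(model_or_T, TransitionModel):
        model = model_or_T
    else:
        T = np.asarray(model_or_T, dtype=float)
        model = TransitionModel(
            T=T,
            lag_time=float(lag_time) if lag_time is not None else 1.0,
            reversible=bool(reversible),
        )
    T = np.asarray(model.T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(T < -1e-12) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("input is not a row-stochastic matrix")
    n = T.shape[0]

    if model.reversible:
        pi = model.stationary if model.stationary is not None else _stationary_from_T(T)
        sqrt_pi = np.sqrt(pi)
        M = (sqrt_pi[:, None] * T) / sqrt_pi[None, :]
        M = 0.5 * (M + M.T)
        values, vectors = scipy.linalg.eigh(M)
        order = np.argsort(values)[::-1]
        values = values[order]
        vectors = vectors[:, order]
        R = vectors / sqrt_pi[:, None]
        L = (vectors * sqrt_pi[:, None]).T
        complex_modes: list[int] = []
    else:
        values, R = np.linalg.eig(T)
        order = np.argsort(values.real)[::-1]
        values = values[order]
        R = R[:, order]
        complex_modes = [i for i, v in enumerate(values) if abs(v.imag) > 1e-12]
        if complex_modes:
            warnings.warn(
                f"non-reversible spectrum has complex eigenvalue pairs at modes "
                f"{complex_modes}; retaining real parts",
                RuntimeWarning,
            )
        L = np.linalg.inv(R)
        values = values.real
        R = R.real
        L = L.real
        pi = model.stationary if model.stationary is not None else _stationary_from_T(T)

    # normalize the stationary pair to (r_0 = ones, l_0 = pi)
    scale = R[:, 0].mean()
    R[:, 0] /= scale
    L[0, :] *= scale
    l0_sum = L[0, :].sum()
    R[:, 0] *= l0_sum
    L[0, :] /= l0_sum

    R, L = _apply_sign_convention(R, L)

    timescales = np.full(n, np.nan)
    for k, mu in enumerate(values):
        if mu >= 1.0 - 1e-12:
            timescales[k] = np.inf
        elif 0.0 < mu < 1.0:
            timescales[k] = -model.lag_time / np.log(mu)

    model.eigenvalues = values
    model.right_eigenvectors = R
    model.left_eigenvectors = L
    model.stationary = pi
    model.implied_timescales = timescales
    return model


# ---------------------------------------------------------------------------
# implied timescale curves and propagation


def implied_timescale_curves(
    label_trajs,
    lags,
    n_timescales: int = 2,
    dt: float = 1.0,
    reversible: bool = True,
    mode: str = "sliding",
) -> pd.DataFrame:
    """Slowest implied timescales versus lag, with the tau_1/tau_2 gap ratio.

    For each lag: count transitions, estimate (reversible MLE by default),
    solve the spectrum and report the ``n_timescales`` slowest relaxation
    timescales in physical units (lag * dt per step).  A flat tau_1(lag)
    with a large gap ratio is the two-state fingerprint.
    """
    lags = list(lags)
    if any(b <= a for a, b in zip(lags, lags[1:])):
        raise ValueError("lags must be strictly ascending")
    rows = []
    for lag in lags:
        cm = count_transitions(label_trajs, lag=lag, mode=mode)
        if reversible:
            model = estimate_reversible_mle(cm, lag_time=lag * dt)
        else:
            model = estimate_nonreversible(cm, lag_time=lag * dt)
        taus = model.implied_timescales[1 : n_timescales + 1]
        row = {"lag": lag, "lag_time": lag * dt}
        for k, tau in enumerate(taus, start=1):
            row[f"tau_{k}"] = tau
        if len(taus) >= 2 and np.isfinite(taus[1]) and taus[1] > 0:
            row["gap_ratio"] = taus[0] / taus[1]
        else:
            row["gap_ratio"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def propagate(model: TransitionModel, p0, n_steps: int) -> list[PopulationVector]:
    """Evolve populations by the eigenmode superposition.

    p(k tau) = sum_n (r_n . p0) mu_n^k l_n, with the stationary term time
    independent.  Equals iterated application of T up to numerical precision;
    the matrix-power route is the cross-check used in the tests.
    """
    if not model.has_spectrum:
        raise ValueError("model spectra are incomplete; run spectral_analysis first")
    p0 = p0.p if isinstance(p0, PopulationVector) else np.asarray(p0, dtype=float)
    if abs(p0.sum() - 1.0) > 1e-10 or np.any(p0 < -1e-12):
        raise ValueError("p0 must be a probability vector")
    amplitudes = model.right_eigenvectors.T @ p0  # (r_n . p0)
    out = [PopulationVector(p0.copy(), time=0.0)]
    for k in range(1, n_steps + 1):
        weights = amplitudes * model.eigenvalues**k
        p = weights @ model.left_eigenvectors
        p = np.clip(p, 0.0, None)
        p /= p.sum()
        out.append(PopulationVector(p, time=k * model.lag_time))
    return out


# ---------------------------------------------------------------------------
# estimator facade


class MarkovStateModel(BaseEstimator):
    """sklearn-style facade: fit a (reversible) MSM from label trajectories.

    Parameters: ``lag`` (frames), ``reversible`` flag, ``dt`` (time per
    frame), counting ``mode``.  Fitted attributes: ``counts_``,
    ``transition_matrix_``, ``eigenvalues_``, ``stationary_``,
    ``timescales_``, ``model_`` (the full :class:`TransitionModel`).
    """

    def __init__(self, lag: int = 1, reversible: bool = True, dt: float = 1.0,
                 mode: str = "sliding"):
        self.lag = lag
        self.reversible = reversible
        self.dt = dt
        self.mode = mode

    def fit(self, label_trajs, y=None):
        cm = count_transitions(label_trajs, lag=self.lag, mode=self.mode)
        if self.reversible:
            model = estimate_reversible_mle(cm, lag_time=self.lag * self.dt)
        else:
            model = estimate_nonreversible(cm, lag_time=self.lag * self.dt)
        self.counts_ = cm
        self.model_ = model
        self.transition_matrix_ = model.T
        self.eigenvalues_ = model.eigenvalues
        self.stationary_ = model.stationary
        self.timescales_ = model.implied_timescales
        return self

    def propagate(self, p0, n_steps: int):
        return propagate(self.model_, p0, n_steps)
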