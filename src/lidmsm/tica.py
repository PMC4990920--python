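"""Time-lagged independent component analysis (tICA).

tICA finds linear combinations of input features with maximal autocorrelation
at a lag time tau, approximating the slowest collective modes of the
dynamics.  It solves the generalized eigenproblem

    C(tau) v = lambda (C(0) + eps I) v

with mean-free, symmetrized covariance estimators pooled over trajectories:
C(0) = <x x^T>, C(tau) = (1/2) <x(t) x(t+tau)^T + x(t+tau) x(t)^T>.
Symmetrization forces a real spectrum (appropriate for reversible dynamics);
the small ridge ``eps`` keeps the problem well posed when some features have
zero variance (frozen coordinates).  Eigenvalues of adequately sampled
reversible data lie in [-1, 1]; in one dimension the single eigenvalue is the
lag-tau autocorrelation.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin

from .featurize import FeatureTrajectory

__all__ = ["TICA", "fit_tica", "project", "Projection"]


def _as_arrays(trajs) -> list[np.ndarray]:
    if isinstance(trajs, (np.ndarray, FeatureTrajectory)):
        trajs = [trajs]
    out = []
    for traj in trajs:
        if isinstance(traj, FeatureTrajectory):
            out.append(traj.values)
        else:
            out.append(np.atleast_2d(np.asarray(traj, dtype=float)))
    return out


class TICA(BaseEstimator, TransformerMixin):
    """Slow linear collective coordinates at a fixed lag.

    Parameters
    ----------
    lag : lag time in frames (default 1, i.e. one snapshot).
    n_components : number of components returned by :meth:`transform`
        (default: all).
    regularization : ridge added to C(0); ``"auto"`` uses
        ``1e-10 * trace(C0) / n_features``, which survives zero-variance
        features while perturbing the spectrum negligibly.  Pass 0 to disable
        (raises a conditioning error naming zero-variance features if C0 is
        singular).

    Attributes (after :meth:`fit`)
    ------------------------------
    mean_ : pooled feature mean.
    c0_, ctau_ : instantaneous and symmetrized time-lagged covariances.
    eigenvalues_ : descending; components_ : generalized eigenvectors as
    columns, normalized so ``V^T C0 V = I``, each with its largest-magnitude
    loading positive (deterministic sign convention).
    """

    def __init__(self, lag: int = 1, n_components: int | None = None,
                 regularization="auto"):
        self.lag = lag
        self.n_components = n_components
        self.regularization = regularization

    def fit(self, X, y=None):
        trajs = _as_arrays(X)
        lag = int(self.lag)
        if lag < 1:
            raise ValueError("lag must be >= 1 frame")
        usable = [t for t in trajs if t.shape[0] > lag]
        if not usable:
            raise ValueError(
                f"no trajectory longer than the lag ({lag} frames); "
                "cannot estimate time-lagged covariances"
            )
        n_features = usable[0].shape[1]
        if any(t.shape[1] != n_features for t in usable):
            raise ValueError("all trajectories must share one feature dimension")

        # Pooled mean over both members of every (t, t+lag) pair, weighting
        # each transition pair equally (matches count weighting downstream).
        total = np.zeros(n_features)
        n_pairs = 0
        for t in usable:
            x0, x1 = t[:-lag], t[lag:]
            total += x0.sum(axis=0) + x1.sum(axis=0)
            n_pairs += x0.shape[0]
        mean = total / (2 * n_pairs)

        c0 = np.zeros((n_features, n_features))
        ctau = np.zeros((n_features, n_features))
        for t in usable:
            x0 = t[:-lag] - mean
            x1 = t[lag:] - mean
            c0 += x0.T @ x0 + x1.T @ x1
            ctau += x0.T @ x1 + x1.T @ x0
        c0 /= 2 * n_pairs
        ctau /= 2 * n_pairs
        ctau = 0.5 * (ctau + ctau.T)  # exact symmetry against roundoff

        if self.regularization == "auto":
            eps = 1e-10 * np.trace(c0) / n_features
        else:
            eps = float(self.regularization)
        if eps == 0.0:
            variances = np.diag(c0)
            dead = np.flatnonzero(variances <= 1e-15 * max(variances.max(), 1.0))
            if dead.size:
                raise ValueError(
                    "instantaneous covariance is singular without regularization; "
                    f"zero-variance feature indices: {dead.tolist()}"
                )
        c0_reg = c0 + eps * np.eye(n_features)

        eigenvalues, vectors = scipy.linalg.eigh(ctau, c0_reg)
        order = np.argsort(eigenvalues)[::-1]
        eigenvalues = eigenvalues[order]
        vectors = vectors[:, order]
        # deterministic sign: largest-magnitude loading positive
        for j in range(vectors.shape[1]):
            k = int(np.argmax(np.abs(vectors[:, j])))
            if vectors[k, j] < 0:
                vectors[:, j] = -vectors[:, j]

        self.mean_ = mean
        self.c0_ = c0
        self.ctau_ = ctau
        self.regularization_ = eps
        self.eigenvalues_ = eigenvalues
        self.components_ = vectors
        self.n_features_in_ = n_features
        return self

    def transform(self, X, n_components: int | None = None) -> np.ndarray:
        if not hasattr(self, "components_"):
            raise ValueError("TICA instance is not fitted yet")
        n = n_components if n_components is not None else self.n_components
        if n is None:
            n = self.components_.shape[1]
        if n > self.components_.shape[1]:
            raise ValueError(
                f"requested {n} components but only "
                f"{self.components_.shape[1]} are available"
            )
        arrays = _as_arrays(X)
        outs = [(a - self.mean_) @ self.components_[:, :n] for a in arrays]
        if isinstance(X, (np.ndarray, FeatureTrajectory)):
            return outs[0]
        return outs


class Projection:
    """Frames projected onto leading tICA components."""

    def __init__(self, values: np.ndarray, lag: int, component_ids=None):
        self.values = np.atleast_2d(np.asarray(values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("projection values must be finite")
        if self.values.shape[1] < 1:
            raise ValueError("need at least one component")
        self.lag = lag
        self.component_ids = (
            list(component_ids)
            if component_ids is not None
            else list(range(self.values.shape[1]))
        )


def fit_tica(trajs, lag: int = 1, regularization="auto") -> TICA:
    """Functional wrapper: fit a :class:`TICA` model on feature trajectories."""
    return TICA(lag=lag, regularization=regularization).fit(trajs)


def project(model: TICA, traj, n_components: int = 2) -> Projection:
    """Project one trajectory onto the leading ``n_components`` components."""
    values = model.transform(traj, n_components=n_components)
    return Projection(values, lag=model.lag, component_ids=list(range(n_components)))
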