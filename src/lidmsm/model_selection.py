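"""GMRQ cross-validation for MSM hyperparameters.

The generalized matrix Rayleigh quotient scores how well the slow subspace
learned on training trajectories generalizes: with A the first m training
eigenvectors expressed on the state basis, S the diagonal state-visit
frequencies of the test set and C the symmetrized test transition
frequencies, the score is

    GMRQ = trace[ (A^T S A)^(-1) (A^T C A) ]

i.e. a sum of m generalized Rayleigh quotients.  By the variational
principle of conformation dynamics its expectation never exceeds
1 + sum of the true sub-unit eigenvalues, train scores exceed test scores on
average (overfitting direction), and m = 1 returns exactly 1 (the stationary
mode).  Folds split whole trajectories, never frames, preserving temporal
correlation within each trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import KCenters, KMeansLloyd
from .msm import count_transitions, estimate_nonreversible, estimate_reversible_mle
from .tica import TICA

__all__ = ["GmrqResult", "gmrq_score", "score_msm_on_labels", "cross_validate"]


@dataclass
class GmrqResult:
    """Grid of hyperparameter settings with per-fold train/test GMRQ scores."""

    table: pd.DataFrame
    n_modes: int
    fold_assignments: dict[int, int]
    seed: int
    best_setting: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        keys = [c for c in self.table.columns if c not in ("fold", "train", "test")]
        return (
            self.table.groupby(keys, dropna=False)
            .agg(train_mean=("train", "mean"), train_sd=("train", "std"),
                 test_mean=("test", "mean"), test_sd=("test", "std"))
            .reset_index()
        )


def _test_frequency_matrices(label_trajs, n_states: int, lag: int):
    cm = count_transitions(label_trajs, lag=lag, n_states=n_states, trim=False)
    N = cm.counts.astype(float)
    total = N.sum()
    if total == 0:
        raise ValueError("test set contains no transition pairs at this lag")
    C = (N + N.T) / (2.0 * total)
    S = np.diag(C.sum(axis=1))
    return S, C


def gmrq_score(A: np.ndarray, S: np.ndarray, C: np.ndarray,
               pseudocount: float = 1e-10) -> float:
    """trace[(A^T S A)^{-1} (A^T C A)] with a documented singularity fallback.

    If some training state is never visited in the test set the overlap
    A^T S A can be singular; a ``pseudocount`` ridge is added with a warning
    rather than failing the fold.
    """
    ASA = A.T @ S @ A
    ACA = A.T @ C @ A
    try:
        if np.linalg.cond(ASA) > 1e12:
            raise np.linalg.LinAlgError("singular overlap")
        solved = np.linalg.solve(ASA, ACA)
    except np.linalg.LinAlgError:
        solved = None
    if solved is None or not np.all(np.isfinite(solved)):
        warnings.warn(
            "singular test overlap (training state unvisited in test); "
            f"adding {pseudocount} to the diagonal",
            RuntimeWarning,
        )
        solved = np.linalg.solve(ASA + pseudocount * np.eye(ASA.shape[0]), ACA)
    return float(np.trace(solved))


def score_msm_on_labels(train_model, test_label_trajs, m: int,
                        n_states: int | None = None) -> float:
    """Score a fitted transition model's first m modes on held-out label data.

    ``train_model`` is a :class:`~lidmsm.msm.TransitionModel`; its right
    eigenvectors live on the trimmed state set and are lifted back to the
    full state basis (zero on trimmed-away states).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > train_model.n_states:
        raise ValueError(f"m ({m}) exceeds the number of states")
    labels = train_model.state_labels or list(range(train_model.n_states))
    if n_states is None:
        n_states = max(
            max(labels) + 1,
            max(int(np.max(t)) + 1 for t in test_label_trajs),
        )
    A = np.zeros((n_states, m))
    A[labels, :] = train_model.right_eigenvectors[:, :m]
    S, C = _test_frequency_matrices(test_label_trajs, n_states,
                                    int(round(train_model.lag_time)))
    return gmrq_score(A, S, C)


def _fit_setting(feature_trajs, setting: dict):
    """features -> tICA -> clustering -> label trajectories + MSM."""
    lag = int(setting.get("lag", 1))
    n_tics = int(setting.get("n_tics", 2))
    tica = TICA(lag=int(setting.get("tica_lag", 1))).fit(feature_trajs)
    projections = [tica.transform(t, n_components=n_tics) for t in feature_trajs]
    pooled = np.vstack(projections)
    method = setting.get("method", "kcenters")
    k = int(setting.get("k", 50))
    if method == "kcenters":
        clusterer = KCenters(k=k).fit(pooled)
    elif method == "kmeans":
        clusterer = KMeansLloyd(k=k).fit(pooled)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    labeller = lambda proj: clusterer.predict(proj)  # noqa: E731
    label_trajs = [labeller(p) for p in projections]
    return tica, clusterer, label_trajs, lag


def cross_validate(
    trajs,
    grid,
    n_folds: int = 5,
    m: int = 3,
    seed: int = 0,
    reversible: bool = True,
    precomputed_labels: bool = False,
) -> GmrqResult:
    """Trajectory-level shuffled k-fold GMRQ cross-validation over a grid.

    ``trajs`` are feature trajectories (or, with ``precomputed_labels``,
    integer label trajectories scored over a grid of lags only).  Settings
    that fail on a fold are recorded with NaN scores, never dropped silently.
    Default m = 3 modes: the stationary mode plus two slow relaxations.
    """
    trajs = list(trajs)
    if len(trajs) < 2:
        raise ValueError("need at least two trajectories to cross-validate")
    if n_folds > len(trajs):
        raise ValueError("n_folds may not exceed the number of trajectories")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trajs))
    fold_of = {int(traj): int(i % n_folds) for i, traj in enumerate(order)}

    rows = []
    for setting in grid:
        for fold in range(n_folds):
            train = [trajs[i] for i in range(len(trajs)) if fold_of[i] != fold]
            test = [trajs[i] for i in range(len(trajs)) if fold_of[i] == fold]
            row = dict(setting)
            row["fold"] = fold
            try:
                if precomputed_labels:
                    lag = int(setting.get("lag", 1))
                    train_labels, test_labels = train, test
                    clusterer = None
                else:
                    _, clusterer, train_labels, lag = _fit_setting(train, setting)
                cm = count_transitions(train_labels, lag=lag)
                est = estimate_reversible_mle if reversible else estimate_nonreversible
                model = est(cm, lag_time=lag)
                if not precomputed_labels:
                    n_tics = int(setting.get("n_tics", 2))
                    tica = TICA(lag=int(setting.get("tica_lag", 1))).fit(train)
                    test_labels = [
                        clusterer.predict(tica.transform(t, n_components=n_tics))
                        for t in test
                    ]
                row["train"] = score_msm_on_labels(model, train_labels, m=m)
                row["test"] = score_msm_on_labels(model, test_labels, m=m)
            except (ValueError, RuntimeError) as exc:
                warnings.warn(f"setting {setting} failed on fold {fold}: {exc}",
                              RuntimeWarning)
                row["train"] = np.nan
                row["test"] = np.nan
            rows.append(row)

    table = pd.DataFrame(rows)
    by_setting = table.groupby(
        [c for c in table.columns if c not in ("fold", "train", "test")],
        dropna=False,
    )["test"].mean()
    best = by_setting.idxmax()
    keys = [c for c in table.columns if c not in ("fold", "train", "test")]
    if not isinstance(best, tuple):
        best = (best,)
    best_setting = dict(zip(keys, best))
    return GmrqResult(table=table, n_modes=m, fold_assignments=fold_of,
                      seed=seed, best_setting=best_setting)
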