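"""Bayesian agglomerative coarse-graining of microstates (BACE-style).

Microstates are merged bottom-up: at each step the connected pair whose
outgoing transition distributions are hardest to tell apart - the smallest
log Bayes factor

    ln BF(i, j) = sum_k [ C_ik ln(p_ik / q_k) + C_jk ln(p_jk / q_k) ]

with p the states' own outgoing probability rows and q the count-weighted
row of the hypothetical merged state - is fused, counts are re-aggregated,
and the procedure repeats until the requested number of macrostates remains.
This is the leading log-likelihood-ratio term of the Bayes factor between
the "two distinct states" and "one merged state" models.  Only pairs with at
least one observed transition between them are merge candidates, which keeps
kinetically disconnected states apart.  The merge sequence is deterministic
(ties broken by the lowest index pair).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msm import CountMatrix

__all__ = ["MacrostateModel", "bace_merge"]


@dataclass
class MacrostateModel:
    """Microstate -> macrostate lumping with its merge history.

    ``mapping[i]`` is the macrostate of microstate i (macrostates renumbered
    0..n_macrostates-1 by their smallest member).  ``merge_log`` records
    (state_a, state_b, ln_bayes_factor) in merge order, states named by their
    smallest original microstate.  ``coarse_counts`` aggregates the original
    counts exactly (total counts are conserved).
    """

    mapping: np.ndarray
    n_macrostates: int
    merge_log: list[tuple[int, int, float]]
    coarse_counts: CountMatrix


def _log_bayes_factor(C: np.ndarray, i: int, j: int) -> float:
    ci = C[i]
    cj = C[j]
    ni = ci.sum()
    nj = cj.sum()
    q = (ci + cj) / (ni + nj)
    out = 0.0
    mask_i = ci > 0
    mask_j = cj > 0
    out += float(np.sum(ci[mask_i] * np.log((ci[mask_i] / ni) / q[mask_i])))
    out += float(np.sum(cj[mask_j] * np.log((cj[mask_j] / nj) / q[mask_j])))
    return out


def bace_merge(counts, n_macro: int) -> MacrostateModel:
    """Merge microstates down to ``n_macro`` macrostates.

    ``counts`` is a :class:`~lidmsm.msm.CountMatrix` (or a raw count array)
    over a connected state set.  Raises if the count graph's connectivity
    cannot support the requested number of macrostates.
    """
    if isinstance(counts, CountMatrix):
        C = np.asarray(counts.counts, dtype=float).copy()
        lag = counts.lag
        labels = counts.ergodic_subset
    else:
        C = np.asarray(counts, dtype=float).copy()
        lag = 1
        labels = list(range(C.shape[0]))
    n = C.shape[0]
    if n_macro < 1 or n_macro > n:
        raise ValueError(f"n_macro must be in [1, {n}]")

    groups: list[list[int]] = [[i] for i in range(n)]  # original micro indices
    active = list(range(n))
    merge_log: list[tuple[int, int, float]] = []

    while len(active) > n_macro:
        best = None
        for a_pos in range(len(active)):
            for b_pos in range(a_pos + 1, len(active)):
                i, j = active[a_pos], active[b_pos]
                if C[i, j] == 0 and C[j, i] == 0:
                    continue  # kinetically disconnected: not a candidate
                bf = _log_bayes_factor(C, i, j)
                if best is None or bf < best[0] - 1e-15:
                    best = (bf, i, j)
        if best is None:
            raise ValueError(
                f"count graph is disconnected: cannot reach {n_macro} macrostates "
                f"from {len(active)} remaining groups"
            )
        bf, i, j = best
        merge_log.append((min(groups[i]), min(groups[j]), bf))
        # aggregate counts of j into i
        C[i, :] += C[j, :]
        C[:, i] += C[:, j]
        C[j, :] = 0.0
        C[:, j] = 0.0
        groups[i] = sorted(groups[i] + groups[j])
        active.remove(j)

    # renumber macrostates by smallest member
    reps = sorted(active, key=lambda s: min(groups[s]))
    mapping = np.empty(n, dtype=int)
    for macro, state in enumerate(reps):
        for micro in groups[state]:
            mapping[micro] = macro
    coarse = np.zeros((len(reps), len(reps)), dtype=np.int64)
    if isinstance(counts, CountMatrix):
        orig = np.asarray(counts.counts)
    else:
        orig = np.asarray(counts)
    for a in range(n):
        for b in range(n):
            coarse[mapping[a], mapping[b]] += orig[a, b]
    coarse_cm = CountMatrix(
        counts=coarse,
        lag=lag,
        n_states=len(reps),
        ergodic_subset=list(range(len(reps))),
    )
    return MacrostateModel(
        mapping=mapping,
        n_macrostates=len(reps),
        merge_log=merge_log,
        coarse_counts=coarse_cm,
    )
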