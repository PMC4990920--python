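"""Statistics over docking pose tables: outcomes, funnels, enrichment.

Pose tables are tidy tab-separated records (ligand_id, receptor_id,
pose_rank, score, rmsd): lower score is better, rmsd is the heavy-atom
deviation of the docked pose from the crystal pose in Angstrom.  A
(ligand, receptor) cell is a *success* when the best-scoring pose lies
within the threshold (2.0 A by default) of the crystal pose, a *scoring
failure* when some sampled pose does but the best-scoring one does not, and
a *sampling failure* when no pose does.  Ranking receptors by their best
pose score per ligand yields the top-N true-positive enrichment curve.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "SUCCESS_THRESHOLD",
    "classify_outcome",
    "outcome_matrix",
    "pose_rmsd",
    "enrichment_curve",
    "funnel_table",
    "read_dock_records",
    "write_dock_records",
]

#: default pose-success threshold in Angstrom
SUCCESS_THRESHOLD = 2.0

RECORD_COLUMNS = ["ligand_id", "receptor_id", "pose_rank", "score", "rmsd"]

OUTCOMES = ("success", "scoring_failure", "sampling_failure")


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"pose table is missing columns {missing}")
    if (records["rmsd"] < 0).any():
        raise ValueError("pose rmsd must be nonnegative")
    dup = records.duplicated(["ligand_id", "receptor_id", "pose_rank"])
    if dup.any():
        raise ValueError("pose ranks must be unique per (ligand, receptor)")
    return records


def classify_outcome(records: pd.DataFrame, threshold: float = SUCCESS_THRESHOLD) -> str:
    """Outcome class for the poses of one (ligand, receptor) pair."""
    if len(records) == 0:
        raise ValueError("no poses to classify")
    _validate_records(records)
    best = records.loc[records["score"].idxmin()]
    if best["rmsd"] <= threshold:
        return "success"
    if (records["rmsd"] <= threshold).any():
        return "scoring_failure"
    return "sampling_failure"


def outcome_matrix(records: pd.DataFrame, threshold: float = SUCCESS_THRESHOLD) -> pd.DataFrame:
    """Per-(ligand, receptor) best-score rmsd and outcome class.

    The three outcome classes partition all cells.
    """
    _validate_records(records)
    rows = []
    for (ligand, receptor), group in records.groupby(["ligand_id", "receptor_id"]):
        best = group.loc[group["score"].idxmin()]
        rows.append(
            {
                "ligand_id": ligand,
                "receptor_id": receptor,
                "best_score": best["score"],
                "best_score_rmsd": best["rmsd"],
                "outcome": classify_outcome(group, threshold),
            }
        )
    return pd.DataFrame(rows)


def pose_rmsd(pose_coords, reference_coords, correspondence=None) -> float:
    """Root-mean-square deviation between pose and reference, no superposition.

    Docking convention: both structures live in the receptor frame, so no
    alignment is performed.  ``correspondence`` maps pose atom names to
    reference atom names as ``(pose_names, reference_names)``; without it the
    arrays are matched row by row (equal atom counts required).
    """
    pose = np.asarray(getattr(pose_coords, "coord", pose_coords), dtype=float)
    ref = np.asarray(getattr(reference_coords, "coord", reference_coords), dtype=float)
    if correspondence is not None:
        pose_names, ref_names = correspondence
        ref_index = {name: i for i, name in enumerate(ref_names)}
        unmatched = [n for n in pose_names if n not in ref_index]
        if unmatched:
            raise ValueError(f"unmatched atom names: {unmatched}")
        ref = ref[[ref_index[n] for n in pose_names]]
    if pose.shape != ref.shape:
        raise ValueError(
            f"atom count mismatch: pose {pose.shape[0]} vs reference {ref.shape[0]}"
        )
    return float(np.sqrt(np.mean(np.sum((pose - ref) ** 2, axis=1))))


def enrichment_curve(
    records: pd.DataFrame,
    n_list,
    threshold: float = SUCCESS_THRESHOLD,
) -> pd.DataFrame:
    """True-positive rate when only the top-N receptors per ligand are kept.

    For each ligand, receptors are ranked by their best pose score ascending
    (ties broken by receptor id); the ligand counts as correct at N if any of
    its top-N receptors is a success.  TPR(N) is the fraction of ligands
    correct at N; it is non-decreasing in N and reaches the ligand success
    fraction when N covers every receptor.
    """
    outcomes = outcome_matrix(records, threshold)
    n_list = sorted(int(n) for n in n_list)
    per_ligand = {}
    for ligand, group in outcomes.groupby("ligand_id"):
        if len(group) < n_list[-1]:
            raise ValueError(
                f"ligand {ligand!r} has only {len(group)} receptors, "
                f"fewer than max N = {n_list[-1]}"
            )
        ranked = group.sort_values(["best_score", "receptor_id"], kind="mergesort")
        hits = (ranked["outcome"] == "success").to_numpy()
        first = int(np.argmax(hits)) + 1 if hits.any() else np.inf
        per_ligand[ligand] = first
    rows = [
        {
            "N": n,
            "tpr": float(np.mean([first <= n for first in per_ligand.values()])),
        }
        for n in n_list
    ]
    return pd.DataFrame(rows)


def funnel_table(records: pd.DataFrame) -> pd.DataFrame:
    """Flat (ligand, score, rmsd) export plus a per-ligand Spearman correlation.

    A positive score-rmsd rank correlation is the funnel signature: low
    scores predict near-native poses.
    """
    _validate_records(records)
    flat = records[["ligand_id", "receptor_id", "score", "rmsd"]].copy()
    correlations = {}
    for ligand, group in flat.groupby("ligand_id"):
        rho = spearmanr(group["score"], group["rmsd"]).statistic
        correlations[ligand] = float(rho)
    flat["spearman"] = flat["ligand_id"].map(correlations)
    return flat


def write_dock_records(path, records: pd.DataFrame) -> None:
    _validate_records(records)
    records[RECORD_COLUMNS].to_csv(path, sep="\t", index=False)


def read_dock_records(path) -> pd.DataFrame:
    records = pd.read_csv(path, sep="\t")
    return _validate_records(records)
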