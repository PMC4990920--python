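"""Distance featurization and secondary-structure bookkeeping.

Coordinates come in as PDB-format structures (read with biotite) or as bare
numpy arrays; features going into tICA are pairwise C-alpha distances over a
residue selection combining the disordered lid segment with binding-site
residues picked by proximity to a bound ligand.  DSSP letter strings are
consumed (never computed here) and reduced to helix/sheet fractions.

Residue indexing is 1-based throughout, matching PDB numbering of the
construct; distances are in Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ResidueSelection",
    "FeatureTrajectory",
    "select_binding_site",
    "pairwise_ca_distances",
    "ss_fractions",
]

#: DSSP letters counted as helix / sheet.
HELIX_LETTERS = frozenset("GHI")
SHEET_LETTERS = frozenset("BE")

#: Default lid segment: residues 1-24 of the receptor construct.
DEFAULT_LID_RESIDUES = tuple(range(1, 25))


@dataclass
class ResidueSelection:
    """Sorted, duplicate-free lid and binding-site residue index lists (1-based)."""

    lid_residues: list[int]
    site_residues: list[int]
    cutoff: float
    index_base: int = 1

    def __post_init__(self):
        self.lid_residues = sorted(set(int(r) for r in self.lid_residues))
        self.site_residues = sorted(set(int(r) for r in self.site_residues))
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive")

    @property
    def union(self) -> list[int]:
        return sorted(set(self.lid_residues) | set(self.site_residues))


@dataclass
class FeatureTrajectory:
    """Time-ordered frames of real-valued feature vectors with a uniform step.

    ``values`` is (n_frames, n_features); ``dt`` is the time per frame in ps;
    ``feature_labels`` name each column (residue pairs for distance features).
    """

    values: np.ndarray
    dt: float = 100.0
    feature_labels: list = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] < 1:
            raise ValueError("need at least one frame")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if not self.feature_labels:
            self.feature_labels = [f"f{i}" for i in range(self.values.shape[1])]
        if len(self.feature_labels) != self.values.shape[1]:
            raise ValueError("feature_labels length must equal n_features")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def _atoms_of(structure):
    """Return (coords, residue ids) from a biotite AtomArray or a path."""
    if isinstance(structure, (str,)) or hasattr(structure, "__fspath__"):
        from .io import read_pdb_structure

        structure = read_pdb_structure(structure)
    return structure


def select_binding_site(
    receptor_structure,
    ligand_structure,
    cutoff: float = 5.0,
    lid_residues=DEFAULT_LID_RESIDUES,
) -> ResidueSelection:
    """Pick receptor residues with any atom within ``cutoff`` A of any ligand atom.

    The lid segment is caller-supplied (default residues 1-24); the returned
    selection's union of lid and site lists is what featurization uses.
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    receptor = _atoms_of(receptor_structure)
    ligand = _atoms_of(ligand_structure)
    if ligand.array_length() == 0:
        raise ValueError("ligand structure contains no atoms (empty site)")
    dist = cdist(receptor.coord, ligand.coord)
    close = dist.min(axis=1) <= cutoff
    site = sorted(set(int(r) for r in receptor.res_id[close]))
    return ResidueSelection(list(lid_residues), site, cutoff)


def _pair_list(selection: ResidueSelection, pair_rule: str):
    if pair_rule == "all":
        residues = selection.union
        return [
            (residues[i], residues[j])
            for i in range(len(residues))
            for j in range(i + 1, len(residues))
        ]
    if pair_rule == "cross":
        site_only = [r for r in selection.site_residues if r not in selection.lid_residues]
        return [(i, j) for i in selection.lid_residues for j in site_only]
    raise ValueError(f"unknown pair rule {pair_rule!r} (use 'all' or 'cross')")


def pairwise_ca_distances(
    coords,
    selection: ResidueSelection,
    pair_rule: str = "all",
    dt: float = 100.0,
    source_id: str = "",
) -> FeatureTrajectory:
    """Euclidean C-alpha distances for every residue pair under ``pair_rule``.

    ``coords`` may be a biotite AtomArray/AtomArrayStack (CA atoms are located
    by atom name) or a (n_frames, n_residues, 3) array whose second axis is
    indexed by the selection's 1-based residue numbers minus one.

    Pair rules: ``all`` - all unordered pairs over the lid+site union
    (n(n-1)/2 features); ``cross`` - lid x site pairs only.  The rule used is
    recorded in the feature labels' header by callers.
    """
    pairs = _pair_list(selection, pair_rule)
    residues_needed = sorted(set(r for pair in pairs for r in pair))

    if hasattr(coords, "coord"):  # biotite structure
        structure = coords
        if structure.coord.ndim == 2:
            frames = structure.coord[None]
            res_ids = structure.res_id
            atom_names = structure.atom_name
        else:
            frames = structure.coord
            res_ids = structure.res_id
            atom_names = structure.atom_name
        ca_index: dict[int, int] = {}
        for res in residues_needed:
            hits = np.flatnonzero((res_ids == res) & (atom_names == "CA"))
            if hits.size == 0:
                raise ValueError(f"residue {res} has no CA atom in the structure")
            ca_index[res] = int(hits[0])
        ca_coords = frames[:, [ca_index[r] for r in residues_needed], :]
    else:
        frames = np.asarray(coords, dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise ValueError("coords must be (n_frames, n_residues, 3)")
        for res in residues_needed:
            if res - 1 >= frames.shape[1]:
                raise ValueError(
                    f"residue {res} has no CA coordinates (array has "
                    f"{frames.shape[1]} residues)"
                )
        ca_coords = frames[:, [r - 1 for r in residues_needed], :]
        if not np.all(np.isfinite(ca_coords)):
            bad = np.argwhere(~np.isfinite(ca_coords).all(axis=2))
            frame, pos = bad[0]
            raise ValueError(
                f"missing CA coordinates for residue {residues_needed[pos]} "
                f"in frame {frame}"
            )

    col = {res: i for i, res in enumerate(residues_needed)}
    i_idx = np.array([col[a] for a, _ in pairs])
    j_idx = np.array([col[b] for _, b in pairs])
    diffs = ca_coords[:, i_idx, :] - ca_coords[:, j_idx, :]
    values = np.linalg.norm(diffs, axis=2)
    return FeatureTrajectory(
        values=values, dt=dt, feature_labels=list(pairs), source_id=source_id
    )


def ss_fractions(dssp_string: str) -> tuple[float, float]:
    """Helix and sheet fractions of a per-frame DSSP letter string.

    Helix counts letters G, H, I; sheet counts B, E; anything else (including
    unknown characters) is treated as coil.
    """
    if not dssp_string:
        raise ValueError("empty DSSP string")
    n = len(dssp_string)
    helix = sum(1 for ch in dssp_string if ch in HELIX_LETTERS)
    sheet = sum(1 for ch in dssp_string if ch in SHEET_LETTERS)
    return helix / n, sheet / n
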