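"""Residue-contact statistics over regions of the projected landscape.

To characterize what structural changes a slow mode represents, frames are
partitioned into quadrants of the (tIC1, tIC2) plane and, for every residue
pair, a Bayes-factor contact metric compares the odds of the pair being in
contact inside a region against the odds over all frames:

    BF = [f_r / (1 - f_r)] / [f_a / (1 - f_a)]

with pseudocount-smoothed frequencies f = (k + alpha) / (n + 2 alpha)
(alpha = 1 by default).  BF > 1 marks contacts enriched in the region; the
complement identity BF(contact) * BF(no contact) = 1 holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ContactTrajectory",
    "EnrichmentMap",
    "compute_contacts",
    "quadrant_partition",
    "bayes_factor_map",
]

#: default contact cutoffs in Angstrom per definition
DEFAULT_CUTOFFS = {"heavy-atom-min": 4.5, "ca": 8.0}


@dataclass
class ContactTrajectory:
    """Boolean frames x pairs contact matrix with its defining rule."""

    contacts: np.ndarray
    pair_labels: list[tuple[int, int]]
    cutoff: float
    definition: str = "heavy-atom-min"

    def __post_init__(self):
        self.contacts = np.asarray(self.contacts, dtype=bool)
        if self.contacts.ndim != 2:
            raise ValueError("contacts must be frames x pairs")
        if len(self.pair_labels) != self.contacts.shape[1]:
            raise ValueError("pair_labels length must match contact columns")


@dataclass
class EnrichmentMap:
    """Per-pair contact enrichment (odds ratios) for one region."""

    bf: np.ndarray
    pair_labels: list[tuple[int, int]]
    region_id: str
    pseudocount: float = 1.0

    def __post_init__(self):
        self.bf = np.asarray(self.bf, dtype=float)
        if np.any(self.bf <= 0):
            raise ValueError("Bayes factors must be positive (pseudocounts)")


def compute_contacts(
    coords,
    residue_ids,
    pairs,
    cutoff: float | None = None,
    definition: str = "heavy-atom-min",
    elements=None,
) -> ContactTrajectory:
    """Boolean contacts per frame for the requested residue pairs.

    ``coords`` is (n_frames, n_atoms, 3); ``residue_ids`` assigns each atom a
    residue; ``pairs`` lists residue-id pairs.  ``heavy-atom-min`` uses the
    minimum distance over non-hydrogen atoms (``elements`` required to filter
    hydrogens when present); ``ca`` expects one atom per residue already
    (C-alpha traces).  Contact when distance < cutoff.
    """
    if definition not in DEFAULT_CUTOFFS:
        raise ValueError(f"unknown contact definition {definition!r}")
    if cutoff is None:
        cutoff = DEFAULT_CUTOFFS[definition]
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    residue_ids = np.asarray(residue_ids)
    keep = np.ones(residue_ids.shape[0], dtype=bool)
    if definition == "heavy-atom-min" and elements is not None:
        keep = np.asarray([e.upper() != "H" for e in elements])
    atom_of = {}
    for res in set(int(r) for a, b in pairs for r in (a, b)):
        idx = np.flatnonzero((residue_ids == res) & keep)
        if idx.size == 0:
            raise ValueError(f"residue {res} has no atoms for definition {definition!r}")
        atom_of[res] = idx
    n_frames = coords.shape[0]
    out = np.zeros((n_frames, len(pairs)), dtype=bool)
    for p, (a, b) in enumerate(pairs):
        xa = coords[:, atom_of[int(a)], :]
        xb = coords[:, atom_of[int(b)], :]
        diff = xa[:, :, None, :] - xb[:, None, :, :]
        dmin = np.sqrt((diff**2).sum(axis=-1)).min(axis=(1, 2))
        out[:, p] = dmin < cutoff
    return ContactTrajectory(out, [(int(a), int(b)) for a, b in pairs], cutoff, definition)


def quadrant_partition(projection, center: str = "median") -> np.ndarray:
    """Assign each frame a quadrant label 0..3 of the (tIC1, tIC2) plane.

    Quadrants are defined by the signs of the first two components about
    their medians (robust to sign/offset conventions; ``center="zero"``
    uses the origin instead).  Frames exactly on a boundary go to the lower
    quadrant index.  Label encoding: 2 * (tIC2 > c2) + (tIC1 > c1).
    """
    values = projection.values if hasattr(projection, "values") else np.asarray(projection)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[1] < 2:
        raise ValueError("quadrant partition needs at least two components")
    if center == "median":
        c1, c2 = np.median(values[:, 0]), np.median(values[:, 1])
    elif center == "zero":
        c1 = c2 = 0.0
    else:
        raise ValueError("center must be 'median' or 'zero'")
    return (2 * (values[:, 1] > c2) + (values[:, 0] > c1)).astype(int)


def bayes_factor_map(
    contacts: ContactTrajectory,
    region_labels,
    region,
    pseudocount: float = 1.0,
) -> EnrichmentMap:
    """Smoothed odds-ratio enrichment of each contact inside one region.

    f_r is the pseudocount-smoothed in-region contact frequency, f_a the
    frequency over all frames; BF is the ratio of their odds.  A pair with
    identical frequencies gives BF = 1 exactly.
    """
    region_labels = np.asarray(region_labels)
    mask = region_labels == region
    if not mask.any():
        raise ValueError(f"region {region!r} contains no frames")
    alpha = float(pseudocount)
    k_r = contacts.contacts[mask].sum(axis=0).astype(float)
    n_r = float(mask.sum())
    k_a = contacts.contacts.sum(axis=0).astype(float)
    n_a = float(contacts.contacts.shape[0])
    f_r = (k_r + alpha) / (n_r + 2 * alpha)
    f_a = (k_a + alpha) / (n_a + 2 * alpha)
    bf = (f_r / (1.0 - f_r)) / (f_a / (1.0 - f_a))
    return EnrichmentMap(bf, contacts.pair_labels, str(region), alpha)
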