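"""Rotatable-torsion accounting for (rigidified) peptide ligands.

A docking engine cares about two different tallies, and the package keeps
both, as a single table of rules:

``perceived`` - the flexible bonds the engine's perception stage finds in a
fully flexible ligand: every single, acyclic bond between two heavy atoms
with at least two atoms (heavy or hydrogen) riding on each side.  This
excludes trivial rotors such as hydroxyl O-H pivots (one riding hydrogen)
but includes methyl, ammonium and carboxylate-bearing bonds.

``grown`` - the torsions actually sampled by anchor-and-grow around a rigid
anchor: single, acyclic bonds that move at least one heavy atom or at least
one polar hydrogen (on N, O or S).  Pure-carbon methyl rotors are frozen
(they do not change scored interactions), as is the aromatic hydroxyl of
tyrosine (conjugation).

Bonds inside any perceived ring - including the artificial macrocycle of a
rigidified backbone - are rigid under both rules.  When no convention is
given, a cyclized (anchored) peptide is tallied with ``grown`` and a linear
one with ``perceived``, matching what the engine would report in each case.

For the 12-mer p53 transactivation-domain fragment ETFSDLWKLLPE with charged
termini this accounting gives 66 perceived torsions in linear form and 29
grown torsions after terminal-alpha-carbon cyclization; the designed
inhibitor peptide TSFAEYWALLSP gives 21 in cyclized form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .peptide import PeptideTopology

__all__ = ["TorsionCount", "rotatable_bonds", "count_torsions"]

CONVENTIONS = ("perceived", "grown")


@dataclass
class TorsionCount:
    """Total rotatable torsions with a per-category breakdown.

    Categories: backbone phi (N-CA), psi (CA-C), omega (peptide C-N);
    sidechain bonds moving heavy atoms; polar-hydrogen rotors (hydroxyl,
    ammonium); terminal all-hydrogen carbon rotors (methyls; perceived
    convention only).  The total always equals the category sum.
    """

    total: int
    by_category: dict[str, int] = field(default_factory=dict)
    convention: str = "grown"
    bonds: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if self.total != sum(self.by_category.values()):
            raise ValueError("total must equal the sum of categories")
        if any(v < 0 for v in self.by_category.values()):
            raise ValueError("category counts must be nonnegative")


def _side_census(graph: nx.Graph, pivot: str, other: str):
    """Atoms riding a rotation about pivot-other, on the pivot side.

    Riding set: hydrogens on the pivot plus every heavy atom (and its
    hydrogens) beyond the pivot, excluding the axis atoms themselves.
    """
    pruned = graph.copy()
    pruned.remove_edge(pivot, other)
    side = nx.node_connected_component(pruned, pivot)
    heavy = [a for a in side if a != pivot]
    n_h = graph.nodes[pivot]["n_h"] + sum(graph.nodes[a]["n_h"] for a in heavy)
    polar_h = graph.nodes[pivot]["polar_h"] + sum(
        graph.nodes[a]["polar_h"] for a in heavy
    )
    return {
        "heavy": len(heavy),
        "hydrogens": n_h,
        "polar_h": polar_h,
        "riding": len(heavy) + n_h,
        "pivot_element": graph.nodes[pivot]["element"],
        "other_aromatic": graph.nodes[other]["aromatic"],
    }


def _qualifies(census: dict, convention: str) -> bool:
    if convention == "perceived":
        return census["riding"] >= 2
    # grown: must move a heavy atom or a polar hydrogen ...
    if census["heavy"] >= 1:
        return True
    if census["polar_h"] >= 1:
        # ... except a lone hydroxyl on an aromatic carbon (conjugated O-H)
        if census["pivot_element"] == "O" and census["other_aromatic"]:
            return False
        return True
    return False


def _category(graph: nx.Graph, a: str, b: str, side_a: dict, side_b: dict) -> str:
    role_a = graph.nodes[a]["role"]
    role_b = graph.nodes[b]["role"]
    roles = {role_a, role_b}
    if roles == {"N", "CA"}:
        return "backbone_phi"
    if roles == {"CA", "C"}:
        return "backbone_psi"
    if roles == {"C", "N"}:
        return "backbone_omega"
    small = side_a if side_a["riding"] <= side_b["riding"] else side_b
    if small["heavy"] == 0:
        return "polar_hydrogen_rotors" if small["polar_h"] > 0 else "terminal_rotors"
    return "sidechain_heavy"


def rotatable_bonds(topology: PeptideTopology, convention: str) -> list[tuple[str, str]]:
    """All rotatable bonds of the topology under one convention."""
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    graph = topology.graph
    out = []
    for a, b, data in graph.edges(data=True):
        if data["order"] != 1 or data["in_ring"]:
            continue
        side_a = _side_census(graph, a, b)
        side_b = _side_census(graph, b, a)
        if _qualifies(side_a, convention) and _qualifies(side_b, convention):
            out.append((a, b))
    return sorted(out)


def count_torsions(topology: PeptideTopology, convention: str | None = None) -> TorsionCount:
    """Tally rotatable torsions by category.

    With ``convention=None`` the tally follows the ligand's docking setup:
    ``grown`` for a cyclized (backbone-anchored) peptide, ``perceived`` for a
    linear one.
    """
    if convention is None:
        convention = "grown" if topology.cyclized else "perceived"
    bonds = rotatable_bonds(topology, convention)
    categories = {
        "backbone_phi": 0,
        "backbone_psi": 0,
        "backbone_omega": 0,
        "sidechain_heavy": 0,
        "polar_hydrogen_rotors": 0,
        "terminal_rotors": 0,
    }
    graph = topology.graph
    for a, b in bonds:
        side_a = _side_census(graph, a, b)
        side_b = _side_census(graph, b, a)
        categories[_category(graph, a, b, side_a, side_b)] += 1
    return TorsionCount(
        total=len(bonds), by_category=categories, convention=convention, bonds=bonds
    )
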