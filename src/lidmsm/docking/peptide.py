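"""Peptide heavy-atom topology with ring perception and rigidification.

For docking, helical peptide ligands are rigidified by an artificial bond
between the terminal alpha-carbons, which closes a macrocycle through the
whole backbone; docking engines treat closed cycles as rigid, so the
backbone becomes a single anchor while sidechain torsions stay searchable.
(The alternative bond between the backbone N- and C-termini is also
available.)  Ring perception is graph-theoretic: a bond is in a ring iff it
is not a bridge of the bond graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .templates import POLAR_HYDROGEN_HOSTS, SIDECHAINS

__all__ = ["PeptideLigand", "PeptideTopology", "build_peptide_topology", "rigid_segments"]


@dataclass
class PeptideLigand:
    """A peptide ligand described by sequence and terminal/cyclization state.

    ``cyclized`` adds the artificial terminal bond; ``cyclization_bond``
    selects where it goes: ``"ca-ca"`` (terminal alpha-carbons, the default)
    or ``"n-c"`` (backbone N- and C-terminal atoms).
    """

    sequence: str
    n_term: str = "charged"  # charged NH3+ or neutral NH2
    c_term: str = "charged"  # charged COO- or neutral COOH
    cyclized: bool = False
    cyclization_bond: str = "ca-ca"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = [ch for ch in self.sequence if ch not in SIDECHAINS]
        if bad:
            raise ValueError(f"unknown residue letters: {sorted(set(bad))}")
        if self.n_term not in ("charged", "neutral"):
            raise ValueError("n_term must be 'charged' or 'neutral'")
        if self.c_term not in ("charged", "neutral"):
            raise ValueError("c_term must be 'charged' or 'neutral'")
        if self.cyclization_bond not in ("ca-ca", "n-c"):
            raise ValueError("cyclization_bond must be 'ca-ca' or 'n-c'")


class PeptideTopology:
    """Heavy-atom bond graph of a peptide with per-atom hydrogen counts.

    Node attributes: ``element``, ``n_h`` (attached hydrogens), ``polar_h``
    (hydrogens on N/O/S), ``aromatic``, ``residue`` (0-based), ``role``
    (backbone atom name or "sidechain").  Edge attributes: ``order`` and,
    after ring perception, ``in_ring``.
    """

    def __init__(self, graph: nx.Graph, ligand: PeptideLigand):
        self.graph = graph
        self.ligand = ligand
        self._perceive_rings()

    def _perceive_rings(self) -> None:
        bridges = set(frozenset(e) for e in nx.bridges(self.graph))
        for a, b in self.graph.edges:
            self.graph.edges[a, b]["in_ring"] = frozenset((a, b)) not in bridges

    # -- convenience views -------------------------------------------------
    @property
    def cyclized(self) -> bool:
        return self.ligand.cyclized

    def ring_bonds(self) -> list[tuple[str, str]]:
        return [e for e in self.graph.edges if self.graph.edges[e]["in_ring"]]

    def rings(self) -> list[set[str]]:
        """Connected sets of ring atoms (fused rings merge into one set)."""
        ring_graph = self.graph.edge_subgraph(self.ring_bonds())
        return [set(c) for c in nx.connected_components(ring_graph)]

    def macrocycle(self) -> set[str] | None:
        """The ring containing >= 2 alpha-carbons, if any (the backbone cycle)."""
        for ring in self.rings():
            n_ca = sum(1 for a in ring if a.endswith(":CA"))
            if n_ca >= 2:
                return ring
        return None


def _atom(residue: int, name: str) -> str:
    return f"{residue}:{name}"


def build_peptide_topology(ligand: PeptideLigand) -> PeptideTopology:
    """Assemble the heavy-atom bond graph of a peptide from residue templates.

    Backbone atoms N, CA, C, O (plus terminal OXT) are generated per residue
    and joined by peptide bonds; sidechains come from the residue templates;
    the proline ring and all aromatic rings are perceived from the graph, as
    is the artificial macrocycle when ``ligand.cyclized`` is set.
    """
    seq = ligand.sequence
    n_res = len(seq)
    g = nx.Graph()

    for i, letter in enumerate(seq):
        template = SIDECHAINS[letter]
        # backbone
        if i == 0:
            n_h = {"charged": 3, "neutral": 2}[ligand.n_term]
            if letter == "P":  # ring nitrogen: one fewer H
                n_h -= 1
        else:
            n_h = 0 if letter == "P" else 1
        g.add_node(_atom(i, "N"), element="N", n_h=n_h, aromatic=False,
                   residue=i, role="N")
        g.add_node(_atom(i, "CA"), element="C", n_h=2 if letter == "G" else 1,
                   aromatic=False, residue=i, role="CA")
        g.add_node(_atom(i, "C"), element="C", n_h=0, aromatic=False,
                   residue=i, role="C")
        g.add_node(_atom(i, "O"), element="O", n_h=0, aromatic=False,
                   residue=i, role="O")
        g.add_edge(_atom(i, "N"), _atom(i, "CA"), order=1)
        g.add_edge(_atom(i, "CA"), _atom(i, "C"), order=1)
        c_o_order = 2
        if i == n_res - 1:
            # terminal carboxylate (resonant) or acid
            oxt_h = 0 if ligand.c_term == "charged" else 1
            g.add_node(_atom(i, "OXT"), element="O", n_h=oxt_h, aromatic=False,
                       residue=i, role="OXT")
            if ligand.c_term == "charged":
                c_o_order = "ar"
                g.add_edge(_atom(i, "C"), _atom(i, "OXT"), order="ar")
            else:
                g.add_edge(_atom(i, "C"), _atom(i, "OXT"), order=1)
        g.add_edge(_atom(i, "C"), _atom(i, "O"), order=c_o_order)
        if i > 0:
            g.add_edge(_atom(i - 1, "C"), _atom(i, "N"), order=1)  # omega

        # sidechain
        aromatic = set(template["aromatic"])
        for name, (element, hcount) in template["atoms"].items():
            g.add_node(_atom(i, name), element=element, n_h=hcount,
                       aromatic=name in aromatic, residue=i, role="sidechain")
        for a, b, order in template["bonds"]:
            g.add_edge(_atom(i, a), _atom(i, b), order=order)
        if template["atoms"]:
            g.add_edge(_atom(i, "CA"), _atom(i, "CB"), order=1)
        if letter == "P":
            g.add_edge(_atom(i, "CD"), _atom(i, "N"), order=1)  # pyrrolidine ring

    if ligand.cyclized:
        if ligand.cyclization_bond == "ca-ca":
            g.add_edge(_atom(0, "CA"), _atom(n_res - 1, "CA"), order=1,
                       artificial=True)
        else:
            g.add_edge(_atom(0, "N"), _atom(n_res - 1, "C"), order=1,
                       artificial=True)

    # polar hydrogen bookkeeping
    for node, data in g.nodes(data=True):
        data["polar_h"] = data["n_h"] if data["element"] in POLAR_HYDROGEN_HOSTS else 0

    return PeptideTopology(g, ligand)


def rigid_segments(topology: PeptideTopology, min_atoms: int = 5) -> list[set[str]]:
    """Rigid segments with at least ``min_atoms`` heavy atoms (anchor report).

    A rigid segment is a connected component of the bond graph after cutting
    every rotatable bond (grown convention); segments of five or more atoms
    are the candidate anchors a docking engine would orient first.  This is a
    reporting function only - no search is performed.
    """
    from .torsions import rotatable_bonds

    rotatable = set(frozenset(b) for b in rotatable_bonds(topology, "grown"))
    pruned = topology.graph.copy()
    pruned.remove_edges_from([tuple(b) for b in rotatable])
    segments = [set(c) for c in nx.connected_components(pruned)]
    return [s for s in segments if len(s) >= min_atoms]
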