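"""Peptide topology, torsion accounting and docking statistics."""

import numpy as np
import pandas as pd
import pytest

from lidmsm.docking import (
    PeptideLigand,
    build_peptide_topology,
    classify_outcome,
    count_torsions,
    enrichment_curve,
    funnel_table,
    outcome_matrix,
    pose_rmsd,
    rigid_segments,
)
from lidmsm.docking.torsions import rotatable_bonds

P53_SEQ = "ETFSDLWKLLPE"
PMI_SEQ = "TSFAEYWALLSP"


class TestPeptideTopology:
    def test_linear_diglycine_has_no_rings(self):
        top = build_peptide_topology(PeptideLigand("GG"))
        assert top.rings() == []
        assert top.macrocycle() is None

    def test_cyclized_diglycine_forms_one_ring_through_both_ca(self):
        top = build_peptide_topology(PeptideLigand("GG", cyclized=True))
        rings = top.rings()
        assert len(rings) == 1
        assert {"0:CA", "1:CA"} <= rings[0]

    def test_cyclized_p53_macrocycle_contains_all_twelve_ca(self):
        top = build_peptide_topology(PeptideLigand(P53_SEQ, cyclized=True))
        macro = top.macrocycle()
        ca_atoms = {f"{i}:CA" for i in range(12)}
        assert ca_atoms <= macro
        # proline ring perceived separately from the macrocycle
        pro_ring = {f"10:{name}" for name in ("N", "CA", "CB", "CG", "CD")}
        rings = top.rings()
        assert any(pro_ring <= ring and len(ring & ca_atoms) >= 12 for ring in rings) \
            or any(pro_ring <= ring for ring in rings)

    def test_unknown_residue_letter_rejected(self):
        with pytest.raises(ValueError, match="unknown residue"):
            PeptideLigand("AXA")

    def test_n_c_cyclization_variant(self):
        top = build_peptide_topology(
            PeptideLigand("GG", cyclized=True, cyclization_bond="n-c")
        )
        assert top.graph.has_edge("0:N", "1:C")


class TestCountTorsions:
    def test_linear_p53_perceived_torsions(self):
        top = build_peptide_topology(PeptideLigand(P53_SEQ))
        tally = count_torsions(top)
        assert tally.convention == "perceived"
        assert tally.total == 66

    def test_cyclized_p53_grown_torsions(self):
        top = build_peptide_topology(PeptideLigand(P53_SEQ, cyclized=True))
        tally = count_torsions(top)
        assert tally.convention == "grown"
        assert tally.total == 29

    def test_cyclized_pmi_grown_torsions(self):
        top = build_peptide_topology(PeptideLigand(PMI_SEQ, cyclized=True))
        assert count_torsions(top).total == 21

    def test_total_equals_category_sum(self):
        top = build_peptide_topology(PeptideLigand(P53_SEQ, cyclized=True))
        tally = count_torsions(top)
        assert tally.total == sum(tally.by_category.values())

    @pytest.mark.parametrize("convention", ["perceived", "grown"])
    @pytest.mark.parametrize("seq", [P53_SEQ, PMI_SEQ, "GASH", "RQNM"])
    def test_cyclization_decrease_equals_macrocycle_absorption(self, seq, convention):
        linear = build_peptide_topology(PeptideLigand(seq))
        cyclic = build_peptide_topology(PeptideLigand(seq, cyclized=True))
        n_lin = count_torsions(linear, convention).total
        n_cyc = count_torsions(cyclic, convention).total
        assert n_cyc <= n_lin
        macro = cyclic.macrocycle()
        absorbed = [
            bond for bond in rotatable_bonds(linear, convention)
            if bond[0] in macro and bond[1] in macro
        ]
        assert n_lin - n_cyc == len(absorbed)

    def test_dangling_terminal_bonds_stay_rotatable_when_cyclized(self):
        top = build_peptide_topology(PeptideLigand(P53_SEQ, cyclized=True))
        bonds = rotatable_bonds(top, "grown")
        assert ("0:CA", "0:N") in bonds or ("0:N", "0:CA") in bonds
        assert ("11:C", "11:CA") in bonds or ("11:CA", "11:C") in bonds


class TestRigidSegments:
    def test_aromatic_rings_reported_as_anchors(self):
        top = build_peptide_topology(PeptideLigand("GFG"))
        segments = rigid_segments(top, min_atoms=5)
        assert any(any(a.endswith(":CG") for a in seg) and len(seg) >= 6
                   for seg in segments)

    def test_cyclized_backbone_is_one_large_anchor(self):
        top = build_peptide_topology(PeptideLigand("GAGAG", cyclized=True))
        segments = rigid_segments(top, min_atoms=5)
        assert any(sum(a.endswith(":CA") for a in seg) == 5 for seg in segments)


def records_from(rows):
    return pd.DataFrame(rows, columns=["ligand_id", "receptor_id", "pose_rank",
                                       "score", "rmsd"])


class TestClassifyOutcome:
    def test_best_scoring_pose_within_threshold_is_success(self):
        records = records_from([("L", "R", 1, -20.0, 1.2), ("L", "R", 2, -10.0, 6.0)])
        assert classify_outcome(records) == "success"

    def test_good_pose_not_top_scored_is_scoring_failure(self):
        records = records_from([("L", "R", 1, -20.0, 3.5), ("L", "R", 2, -10.0, 1.8)])
        assert classify_outcome(records) == "scoring_failure"

    def test_no_good_pose_is_sampling_failure(self):
        records = records_from([("L", "R", 1, -20.0, 2.1), ("L", "R", 2, -10.0, 4.0)])
        assert classify_outcome(records) == "sampling_failure"

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError, match="no poses"):
            classify_outcome(records_from([]))


class TestPoseRmsd:
    def test_identical_coordinates_give_zero(self):
        coords = np.arange(12.0).reshape(4, 3)
        assert pose_rmsd(coords, coords) == 0.0

    def test_uniform_translation(self):
        coords = np.arange(12.0).reshape(4, 3)
        shifted = coords + np.array([3.0, 0.0, 0.0])
        assert pose_rmsd(shifted, coords) == pytest.approx(3.0)

    def test_matches_per_atom_formula(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(7, 3))
        b = rng.normal(size=(7, 3))
        expected = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
        assert pose_rmsd(a, b) == pytest.approx(expected, abs=1e-12)

    def test_name_correspondence_reorders_reference(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(3, 3))
        names = ["N", "CA", "C"]
        perm = [2, 0, 1]
        pose = ref[perm]
        pose_names = [names[i] for i in perm]
        assert pose_rmsd(pose, ref, (pose_names, names)) == pytest.approx(0.0)

    def test_unmatched_atom_names_listed(self):
        with pytest.raises(ValueError, match="XX"):
            pose_rmsd(np.zeros((1, 3)), np.zeros((1, 3)), (["XX"], ["CA"]))


class TestEnrichment:
    def test_first_success_at_rank_three(self):
        rows = [("L", f"R{i}", 1, float(i), 5.0) for i in range(1, 6)]
        rows[2] = ("L", "R3", 1, 3.0, 1.0)  # success at rank 3
        records = records_from(rows)
        curve = enrichment_curve(records, [2, 3]).set_index("N")["tpr"]
        assert curve[2] == 0.0 and curve[3] == 1.0

    def test_hand_enumerated_four_ligands(self):
        rows = []
        first_success = {"A": 1, "B": 1, "C": 3, "D": 7}
        for ligand, rank in first_success.items():
            for i in range(1, 8):
                rmsd = 1.0 if i == rank else 5.0
                rows.append((ligand, f"R{i}", 1, float(i), rmsd))
        curve = enrichment_curve(records_from(rows), [3]).set_index("N")["tpr"]
        assert curve[3] == pytest.approx(0.75)

    def test_all_failures_give_zero_everywhere(self):
        rows = [("L", f"R{i}", 1, float(i), 9.0) for i in range(1, 6)]
        curve = enrichment_curve(records_from(rows), [1, 3, 5])
        assert (curve["tpr"] == 0.0).all()

    def test_too_few_receptors_rejected(self):
        rows = [("L", "R1", 1, 0.0, 1.0)]
        with pytest.raises(ValueError, match="fewer"):
            enrichment_curve(records_from(rows), [5])


class TestFunnel:
    def test_perfect_funnel_has_unit_spearman(self):
        rows = [("L", f"R{i}", 1, float(i), float(i)) for i in range(10)]
        table = funnel_table(records_from(rows))
        assert np.allclose(table["spearman"], 1.0)

    def test_anticorrelated_records_give_minus_one(self):
        rows = [("L", f"R{i}", 1, float(i), float(10 - i)) for i in range(10)]
        table = funnel_table(records_from(rows))
        assert np.allclose(table["spearman"], -1.0)

    def test_negative_rmsd_rejected(self):
        rows = [("L", "R0", 1, 0.0, -1.0)]
        with pytest.raises(ValueError, match="nonnegative"):
            funnel_table(records_from(rows))

    def test_noisy_funnel_matches_direct_rank_correlation(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(2)
        scores = rng.normal(size=30)
        rmsds = np.abs(scores + 0.5 * rng.normal(size=30))
        rows = [("L", f"R{i:02d}", 1, s, r) for i, (s, r) in
                enumerate(zip(scores, rmsds))]
        table = funnel_table(records_from(rows))
        expected = spearmanr(scores, rmsds).statistic
        assert table["spearman"].iloc[0] == pytest.approx(expected)


class TestOutcomeMatrix:
    def test_classes_partition_all_cells(self):
        rng = np.random.default_rng(3)
        rows = []
        for ligand in "AB":
            for receptor in range(4):
                for rank in range(1, 4):
                    rows.append((ligand, f"R{receptor}", rank,
                                 rng.normal(), float(rng.uniform(0, 5))))
        records = records_from(rows)
        matrix = outcome_matrix(records)
        assert len(matrix) == 8
        assert set(matrix["outcome"]) <= {
            "success", "scoring_failure", "sampling_failure"
        }
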