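import numpy as np
import pytest

from hlarepeat import (Bead, SabPanel, assign_dsa, call_positivity,
                       candidate_residues, flag_self_background, parse_allele,
                       reconstructed_55r_panel, bead_residue_matrix)
from hlarepeat.mismatch import PositionResidue

from conftest import typing


def bead(bid, name, bcm, alpha=None):
    alleles = (parse_allele(name),) if alpha is None else \
        (parse_allele(name), parse_allele(alpha))
    return Bead(bead_id=bid, alleles=alleles, bcm=bcm)


@pytest.fixture
def quoted_panel():
    """Beads with the BCM values quoted in the reanalysis narrative."""
    return SabPanel(sample_id="s1", beads=(
        bead("b1", "DQB1*06:02", 3318, "DQA1*01:01"),
        bead("b2", "DQB1*06:03", 2560, "DQA1*01:01"),
        bead("b3", "DQB1*02:01", 999),
        bead("b4", "DQB1*03:01", 1000),
    ))


class TestPositivity:
    def test_quoted_bcm_values_positive(self, quoted_panel):
        pos, neg = call_positivity(quoted_panel)
        ids = {b.bead_id for b in pos}
        assert "b1" in ids and "b2" in ids

    def test_boundary_999_negative_1000_positive(self, quoted_panel):
        pos, neg = call_positivity(quoted_panel)
        assert "b3" in {b.bead_id for b in neg}
        assert "b4" in {b.bead_id for b in pos}

    def test_partition_exhaustive_and_disjoint(self, quoted_panel):
        pos, neg = call_positivity(quoted_panel)
        assert len(pos) + len(neg) == len(quoted_panel.beads)
        assert not {b.bead_id for b in pos} & {b.bead_id for b in neg}

    def test_threshold_monotonicity(self, quoted_panel):
        """Raising the threshold never adds positives."""
        previous = None
        for thr in (500, 1000, 2000, 3000, 4000):
            panel = SabPanel(sample_id="s", beads=quoted_panel.beads,
                             threshold=thr)
            ids = {b.bead_id for b in call_positivity(panel)[0]}
            if previous is not None:
                assert ids <= previous
            previous = ids


class TestSelfBackground:
    def test_positive_self_bead_flags_panel(self):
        recipient = typing("p:recipient", "recipient", B=["B*44:02"])
        panel = SabPanel(sample_id="s", beads=(
            bead("b1", "B*51:01", 1342),
            bead("b2", "B*44:02", 1364),   # self allele, similar magnitude
        ))
        flagged, reason = flag_self_background(panel, recipient)
        assert flagged and "B*44:02" in reason and "1364" in reason

    def test_self_bead_under_threshold_not_flagged(self):
        recipient = typing("p:recipient", "recipient", B=["B*44:02"])
        panel = SabPanel(sample_id="s", beads=(
            bead("b1", "B*51:01", 1342),
            bead("b2", "B*44:02", 950),
        ))
        assert flag_self_background(panel, recipient) == (False, None)

    def test_ratio_mode_ignores_weak_self_reactivity(self):
        recipient = typing("p:recipient", "recipient", B=["B*44:02"])
        panel = SabPanel(sample_id="s", beads=(
            bead("b1", "B*51:01", 9000),
            bead("b2", "B*44:02", 1100),   # positive but << max
        ))
        assert flag_self_background(panel, recipient, mode="ratio")[0] is False
        assert flag_self_background(panel, recipient, mode="strict")[0] is True


class TestAssignment:
    def test_serologic_lookalike_is_third_party(self, store):
        """A DQ6-group bead allele absent from every subject must not be
        credited to the MSC donor that carries a different DQ6 allele."""
        recipient = typing("p:recipient", "recipient",
                           DQB1=["DQB1*02:01", "DQB1*03:01"])
        kidney = typing("p:kidney", "kidney", DQB1=["DQB1*06:02"])
        msc = typing("p:msc", "msc", DQB1=["DQB1*06:03"])
        panel = SabPanel(sample_id="s", beads=(
            bead("b1", "DQB1*06:04", 2000, "DQA1*01:01"),))
        call = assign_dsa(panel, recipient, kidney, msc)
        assert call.assignments["b1"] == "third-party"

    def test_direct_identity_assignments(self, store):
        recipient = typing("p:recipient", "recipient", DQB1=["DQB1*02:01"])
        kidney = typing("p:kidney", "kidney", DQB1=["DQB1*06:02"])
        msc = typing("p:msc", "msc", DQB1=["DQB1*06:03", "DQB1*06:02"])
        panel = SabPanel(sample_id="s", beads=(
            bead("b-kid-and-msc", "DQB1*06:02", 3000),
            bead("b-msc", "DQB1*06:03", 2500),
            bead("b-self", "DQB1*02:01", 100),
            bead("b-third", "DQB1*04:01", 1500),
        ))
        call = assign_dsa(panel, recipient, kidney, msc)
        assert call.assignments == {"b-kid-and-msc": "shared",
                                    "b-msc": "msc-donor",
                                    "b-third": "third-party"}
        assert not call.background

    def test_assignment_matches_membership_brute_force(self, store, pool):
        from hlarepeat import SimulationConfig, simulate_sab, simulate_triads
        cohort = simulate_triads(pool, SimulationConfig(n_patients=6, seed=23))
        for i, triad in enumerate(cohort.triads):
            panel, truth = simulate_sab(triad, "none", pool, seed=100 + i)
            # force every bead positive so all assignments are exercised
            forced = SabPanel(sample_id=panel.sample_id, threshold=1.0,
                              beads=panel.beads)
            call = assign_dsa(forced, triad.recipient, triad.kidney, triad.msc)
            for bid, label in call.assignments.items():
                assert label == truth["intended_assignment"][bid]

    def test_kidney_donor_assignment_soundness(self, store, pool):
        from hlarepeat import SimulationConfig, simulate_sab, simulate_triads
        cohort = simulate_triads(pool, SimulationConfig(n_patients=4, seed=29))
        for triad in cohort.triads:
            panel, _ = simulate_sab(triad, "none", pool, seed=3)
            forced = SabPanel(sample_id="f", threshold=1.0, beads=panel.beads)
            call = assign_dsa(forced, triad.recipient, triad.kidney, triad.msc)
            for b in forced.beads:
                if call.assignments[b.bead_id] == "kidney-donor":
                    assert triad.kidney.carries(b.primary)
                    assert not triad.recipient.carries(b.primary)


class TestCandidateResidues:
    def test_55r_uniquely_shared(self, store):
        panel, recipient = reconstructed_55r_panel()
        strict, lenient = candidate_residues(panel, recipient, store, "DQB")
        assert PositionResidue("DQB", 55, "R") in strict
        assert set(strict) <= set(lenient)

    def test_candidates_verifiably_on_positives_off_recipient(self, store):
        panel, recipient = reconstructed_55r_panel()
        positives, _ = call_positivity(panel)
        _, lenient = candidate_residues(panel, recipient, store, "DQB")
        for cand in lenient:
            for b in positives:
                a = b.allele_for_group("DQB")
                assert store.residue_at(a, cand.position) == cand.residue
            for alls in recipient.alleles.values():
                for ra in alls:
                    assert store.residue_at(ra, cand.position) != cand.residue

    def test_single_self_positive_bead_gives_empty_set(self, store):
        recipient = typing("p:recipient", "recipient", DQB1=["DQB1*03:01"])
        panel = SabPanel(sample_id="s", beads=(
            bead("b1", "DQB1*03:01", 2000),))
        strict, lenient = candidate_residues(panel, recipient, store, "DQB")
        assert strict == [] and lenient == []

    def test_no_positive_beads_empty_not_error(self, store):
        recipient = typing("p:recipient", "recipient", DQB1=["DQB1*03:01"])
        panel = SabPanel(sample_id="s", beads=(
            bead("b1", "DQB1*06:02", 100),))
        assert candidate_residues(panel, recipient, store, "DQB") == ([], [])

    def test_strict_subset_of_lenient_on_random_panels(self, store, pool):
        from hlarepeat import SimulationConfig, choose_implant, simulate_sab, \
            simulate_triads
        cohort = simulate_triads(pool, SimulationConfig(n_patients=8, seed=31))
        for i, triad in enumerate(cohort.triads):
            imp = choose_implant(triad, store, "DQB", seed=i)
            panel, _ = simulate_sab(triad, "implant", pool, seed=i, implant=imp)
            strict, lenient = candidate_residues(panel, triad.recipient,
                                                 store, "DQB")
            assert set(strict) <= set(lenient)


def test_bead_residue_matrix_shape(store):
    panel, recipient = reconstructed_55r_panel()
    mat = bead_residue_matrix(panel, store, "DQB")
    assert len(mat) == len(panel.beads)
    assert {"allele", "bcm", "positive"} <= set(mat.columns)
    assert 55 in mat.columns
    pos_rows = mat[mat["positive"]]
    assert set(pos_rows[55]) == {"R"}
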