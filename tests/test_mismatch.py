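import numpy as np
import pytest

from hlarepeat import analyze_triad, parse_allele
from hlarepeat.mismatch import (LOCUS_GROUPS, SPLIT_LOCI, PositionResidue,
                                aa_mismatches, repeated_mismatches,
                                split_mismatches, triad_table)
from hlarepeat.oracle import (brute_aa_mismatches, brute_split_mismatches,
                              brute_triad)
from hlarepeat.store import UnknownAlleleError

from conftest import typing


def random_typing(rng, store, subject_id, role, loci=("A", "B", "C", "DRB1",
                                                      "DQB1"), n_alleles=2):
    alleles = {}
    for locus in loci:
        pool = sorted(a for a in store.sequences if a.locus == locus)
        picks = rng.choice(len(pool), size=n_alleles, replace=True)
        alleles[locus] = tuple(pool[i] for i in picks)
    from hlarepeat import HLATyping
    return HLATyping(subject_id=subject_id, role=role, alleles=alleles)


class TestSplitMismatches:
    def test_dq7_recipient_dq8_donor(self, store):
        rec = typing("p:recipient", "recipient", DQB1=["DQB1*03:01"])
        don = typing("p:kidney", "kidney", DQB1=["DQB1*03:02"])
        mm = split_mismatches(rec, don, store)
        assert mm["DQ"] == {"DQ8"} and len(mm["DQ"]) == 1

    def test_identical_typings_no_mismatch(self, store, pool):
        rng = np.random.default_rng(0)
        t = random_typing(rng, store, "s:recipient", "recipient")
        same = random_typing(np.random.default_rng(0), store, "s:kidney",
                             "kidney")
        mm = split_mismatches(t, same, store)
        assert all(len(v) == 0 for v in mm.values())

    def test_homozygous_donor_antigen_counts_once(self, store):
        rec = typing("p:recipient", "recipient", DQB1=["DQB1*03:01"])
        don = typing("p:kidney", "kidney",
                     DQB1=["DQB1*03:02", "DQB1*03:02"])
        assert split_mismatches(rec, don, store)["DQ"] == {"DQ8"}

    def test_null_allele_excluded_from_donor_set(self, hand_store):
        rec = typing("p:recipient", "recipient", A=["A*01:01"])
        don = typing("p:kidney", "kidney", A=["A*02:01N", "A*01:01"])
        assert split_mismatches(rec, don, hand_store)["A"] == frozenset()

    def test_matches_brute_force_on_random_typings(self, store):
        rng = np.random.default_rng(42)
        for i in range(100):
            rec = random_typing(rng, store, "r:recipient", "recipient")
            don = random_typing(rng, store, "d:kidney", "kidney")
            assert split_mismatches(rec, don, store) == \
                brute_split_mismatches(rec, don, store)


class TestAaMismatches:
    def test_self_comparison_is_empty(self, store):
        rng = np.random.default_rng(1)
        rec = random_typing(rng, store, "s:recipient", "recipient")
        don = random_typing(np.random.default_rng(1), store, "s:msc", "msc")
        mm = aa_mismatches(rec, don, store)
        assert all(len(v) == 0 for v in mm.values())

    def test_hand_enumerated_class_i(self, hand_store):
        """10-position fixture with hand-placed polymorphisms: the mismatch
        set can be read directly off the alignment text."""
        rec = typing("p:recipient", "recipient", A=["A*01:01", "A*02:01"])
        don = typing("p:kidney", "kidney", A=["A*03:01", "A*24:02"])
        mm = aa_mismatches(rec, don, hand_store)
        assert mm["class_I"] == {PositionResidue("class_I", 10, "V"),
                                 PositionResidue("class_I", 7, "M")}

    def test_hand_enumerated_dqb_interlocus(self, hand_store):
        rec = typing("p:recipient", "recipient",
                     DQB1=["DQB1*05:01"], DRB1=["DRB1*01:01"])
        don = typing("p:kidney", "kidney", DQB1=["DQB1*06:02"])
        mm = aa_mismatches(rec, don, hand_store)
        assert mm["DQB"] == {PositionResidue("DQB", 3, "L"),
                             PositionResidue("DQB", 7, "F")}

    def test_scope_law_interlocus_subset_of_intralocus(self, hand_store):
        """A DRB1 allele carrying the donor's residue rescues it only under
        the interlocus scope."""
        rec = typing("p:recipient", "recipient",
                     DQB1=["DQB1*05:01"], DRB1=["DRB1*04:01"])
        don = typing("p:kidney", "kidney", DQB1=["DQB1*06:02"])
        inter = aa_mismatches(rec, don, hand_store, scope="interlocus")
        intra = aa_mismatches(rec, don, hand_store, scope="intralocus")
        assert inter["DQB"] == {PositionResidue("DQB", 7, "F")}
        assert intra["DQB"] == {PositionResidue("DQB", 3, "L"),
                                PositionResidue("DQB", 7, "F")}
        assert inter["DQB"] <= intra["DQB"]

    def test_scope_law_on_random_typings(self, store):
        rng = np.random.default_rng(7)
        for _ in range(50):
            rec = random_typing(rng, store, "r:recipient", "recipient")
            don = random_typing(rng, store, "d:msc", "msc")
            inter = aa_mismatches(rec, don, store, scope="interlocus")
            intra = aa_mismatches(rec, don, store, scope="intralocus")
            for g in LOCUS_GROUPS:
                assert inter[g] <= intra[g]

    def test_unknown_donor_residue_never_mismatches(self, store):
        """A*26:01 has an unresolved residue at masked position 9; it must
        contribute no mismatch there whatever the recipient."""
        rec = typing("p:recipient", "recipient", A=["A*01:01"])
        don = typing("p:kidney", "kidney", A=["A*26:01", "A*26:01"])
        mm = aa_mismatches(rec, don, store)
        assert not any(p.position == 9 for p in mm["class_I"])

    def test_monotonicity_adding_recipient_allele(self, store):
        """A second recipient allele can only remove mismatches."""
        rng = np.random.default_rng(11)
        loci = ("A", "B", "C", "DRB1", "DQB1")
        for _ in range(50):
            rec1 = random_typing(rng, store, "r:recipient", "recipient",
                                 n_alleles=1)
            don = random_typing(rng, store, "d:kidney", "kidney")
            locus = loci[rng.integers(len(loci))]
            pool = sorted(a for a in store.sequences if a.locus == locus)
            extra = pool[rng.integers(len(pool))]
            from hlarepeat import HLATyping
            alleles = dict(rec1.alleles)
            alleles[locus] = alleles[locus] + (extra,)
            rec2 = HLATyping("r:recipient", "recipient", alleles)
            m1 = aa_mismatches(rec1, don, store)
            m2 = aa_mismatches(rec2, don, store)
            s1 = split_mismatches(rec1, don, store)
            s2 = split_mismatches(rec2, don, store)
            for g in LOCUS_GROUPS:
                assert m2[g] <= m1[g]
            for lo in SPLIT_LOCI:
                assert len(s2[lo]) <= len(s1[lo])

    def test_order_invariance(self, store):
        rec = typing("p:recipient", "recipient",
                     DQB1=["DQB1*02:01", "DQB1*03:01"])
        rec_swapped = typing("p:recipient", "recipient",
                             DQB1=["DQB1*03:01", "DQB1*02:01"])
        don = typing("p:kidney", "kidney", DQB1=["DQB1*06:02", "DQB1*04:01"])
        assert aa_mismatches(rec, don, store) == \
            aa_mismatches(rec_swapped, don, store)

    def test_missing_sequence_raises_naming_allele(self, hand_store):
        rec = typing("p:recipient", "recipient", A=["A*01:01"])
        don = typing("p:kidney", "kidney", A=["A*11:01"])  # not in hand store
        with pytest.raises(UnknownAlleleError, match="A\\*11:01"):
            aa_mismatches(rec, don, hand_store)


class TestRepeatedMismatches:
    def test_hand_triad(self, hand_store):
        rec = typing("p:recipient", "recipient",
                     DQB1=["DQB1*05:01"], DRB1=["DRB1*01:01"])
        kid = typing("p:kidney", "kidney", DQB1=["DQB1*06:02"])
        msc = typing("p:msc", "msc", DQB1=["DQB1*06:03"])
        rep = repeated_mismatches(rec, kid, msc, hand_store)
        assert rep.repeated_split["DQ"] == {"DQ6"}
        assert rep.repeated_aa["DQB"] == {PositionResidue("DQB", 3, "L")}

    def test_msc_equal_to_kidney_repeats_everything(self, store):
        from hlarepeat import HLATyping
        rng = np.random.default_rng(5)
        rec = random_typing(rng, store, "p:recipient", "recipient")
        kid = random_typing(rng, store, "p:kidney", "kidney")
        msc = HLATyping("p:msc", "msc", kid.alleles)
        rep = repeated_mismatches(rec, kid, msc, store)
        assert rep.repeated_split == rep.kidney.split
        assert rep.repeated_aa == rep.kidney.aa

    def test_subset_law_and_oracle_equivalence(self, store):
        rng = np.random.default_rng(13)
        for _ in range(100):
            rec = random_typing(rng, store, "p:recipient", "recipient")
            kid = random_typing(rng, store, "p:kidney", "kidney")
            msc = random_typing(rng, store, "p:msc", "msc")
            rep = repeated_mismatches(rec, kid, msc, store)
            truth = brute_triad(rec, kid, msc, store)
            assert rep.repeated_split == truth["repeated_split"]
            assert rep.repeated_aa == truth["repeated_aa"]
            for lo in SPLIT_LOCI:
                assert rep.repeated_split[lo] <= rep.kidney.split[lo]
                assert rep.repeated_split[lo] <= rep.msc.split[lo]
            for g in LOCUS_GROUPS:
                assert rep.repeated_aa[g] <= rep.kidney.aa[g]
                assert rep.repeated_aa[g] <= rep.msc.aa[g]

    def test_kidney_msc_swap_symmetry(self, store):
        rng = np.random.default_rng(17)
        rec = random_typing(rng, store, "p:recipient", "recipient")
        a = random_typing(rng, store, "p:kidney", "kidney")
        b = random_typing(rng, store, "p:msc", "msc")
        fwd = repeated_mismatches(rec, a, b, store)
        from hlarepeat import HLATyping
        a2 = HLATyping("p:msc", "msc", a.alleles)
        b2 = HLATyping("p:kidney", "kidney", b.alleles)
        rev = repeated_mismatches(rec, b2, a2, store)
        assert fwd.repeated_split == rev.repeated_split
        assert fwd.repeated_aa == rev.repeated_aa
        assert fwd.kidney.aa == rev.msc.aa and fwd.msc.aa == rev.kidney.aa


class TestTriadTable:
    def test_hand_counts(self, hand_store):
        rec = typing("p:recipient", "recipient",
                     DQB1=["DQB1*05:01"], DRB1=["DRB1*01:01"])
        kid = typing("p:kidney", "kidney", DQB1=["DQB1*06:02"])
        msc = typing("p:msc", "msc", DQB1=["DQB1*06:03"])
        rep = repeated_mismatches(rec, kid, msc, hand_store, patient_id="p")
        table = triad_table([rep])
        block = table.set_index("comparison")
        assert block.loc["kidney", "DQ"] == 1
        assert block.loc["repeated", "DQ"] == 1
        assert block.loc["kidney", "aa_DQB"] == 2
        assert block.loc["msc", "aa_DQB"] == 2
        assert block.loc["repeated", "aa_DQB"] == 1

    def test_no_mismatch_triad_gives_zero_rows(self, store):
        rec = typing("p:recipient", "recipient", DQB1=["DQB1*03:01"])
        rep = repeated_mismatches(
            rec, typing("p:kidney", "kidney", DQB1=["DQB1*03:01"]),
            typing("p:msc", "msc", DQB1=["DQB1*03:01"]), store)
        table = triad_table([rep])
        counts = table.drop(columns=["patient_id", "comparison"])
        assert (counts == 0).all().all()

    def test_identical_triads_identical_blocks(self, store):
        from hlarepeat import worked_example_triad
        r1 = analyze_triad(worked_example_triad(), store)
        r2 = analyze_triad(worked_example_triad(), store)
        tab = triad_table([r1, r2])
        b1 = tab.iloc[:3].drop(columns="patient_id").reset_index(drop=True)
        b2 = tab.iloc[3:].drop(columns="patient_id").reset_index(drop=True)
        assert b1.equals(b2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            triad_table([])
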