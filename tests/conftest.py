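import pytest

from hlarepeat import (AllelePool, HLATyping, load_packaged_store,
                       parse_allele)
from hlarepeat.store import (AccessibilityMask, SerologyMap, build_store,
                             load_alignment)


@pytest.fixture(scope="session")
def store():
    return load_packaged_store()


@pytest.fixture(scope="session")
def pool(store):
    return AllelePool.from_store(store)


def typing(subject_id, role, **loci):
    """Shorthand: typing('p:recipient', 'recipient', DQB1=['DQB1*03:01'])."""
    return HLATyping(
        subject_id=subject_id, role=role,
        alleles={lo: tuple(parse_allele(n) for n in names)
                 for lo, names in loci.items()})


# ---------------------------------------------------------------------------
# a hand-enumerable 10-position fixture: two loci, polymorphisms placed by
# hand so expected mismatch sets can be read off the alignment text
# ---------------------------------------------------------------------------

HAND_A = """\
A*01:01 ARNDCQEGHI
A*02:01 -K---W----
A*03:01 -K-------V
A*24:02 ---*--M---
"""

HAND_DQB1 = """\
DQB1*05:01 MFPSTWYVAG
DQB1*06:02 --L---F---
DQB1*06:03 --L----N--
"""

HAND_DRB1 = """\
DRB1*01:01 MFPSTWYVAG
DRB1*04:01 --L-----Q-
"""

HAND_MASK_POSITIONS = {"A": frozenset({2, 3, 6, 7, 10}),
                       "DQB1": frozenset({3, 7, 8, 9}),
                       "DRB1": frozenset({3, 7, 8, 9})}

HAND_SEROLOGY = {
    "A*01:01": "A1", "A*02:01": "A2", "A*03:01": "A3", "A*24:02": "A24",
    "DQB1*05:01": "DQ5", "DQB1*06:02": "DQ6", "DQB1*06:03": "DQ6",
    "DRB1*01:01": "DR1", "DRB1*04:01": "DR4",
}


@pytest.fixture(scope="session")
def hand_store():
    alignments = [load_alignment(HAND_A, locus="A"),
                  load_alignment(HAND_DQB1, locus="DQB1"),
                  load_alignment(HAND_DRB1, locus="DRB1")]
    mask = AccessibilityMask(positions=HAND_MASK_POSITIONS,
                             version="hand-mask-1")
    serology = SerologyMap(
        split={parse_allele(a): s for a, s in HAND_SEROLOGY.items()},
        version="hand-serology-1")
    return build_store(alignments, mask, serology)
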