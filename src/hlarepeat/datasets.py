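"""Packaged synthetic reference data and ready-made example inputs.

The shipped alignments, mask and serology map are a small SYNTHETIC
stand-in for the real immunogenetics reference databases (full protein
alignments and the published solvent-accessibility definition), which are
not redistributed here. The DQB1 fixture is constructed so that documented
domain facts hold: the DQ5/DQ6/DQ4-group alleles (including DQB1*06:02 and
DQB1*06:03) carry arginine at beta-chain position 55 while the DQ2/DQ7/DQ8
alleles do not, and the DQ7/DQ8/DQ4 worked-example triad has no repeated
split mismatch but three repeated amino-acid mismatches. Toy 12-position
class I and DRB loci support the cohort simulator.
"""
from __future__ import annotations

from importlib import resources

from .nomenclature import parse_allele
from .sab import Bead, SabPanel
from .store import (AlleleStore, build_store, load_alignment, load_mask,
                    load_serology)
from .subjects import HLATyping, Triad

_LOCUS_FILES = {
    "A": "a_synthetic_prot.txt",
    "B": "b_synthetic_prot.txt",
    "C": "c_synthetic_prot.txt",
    "DRB1": "drb1_synthetic_prot.txt",
    "DRB3": "drb3_synthetic_prot.txt",
    "DQA1": "dqa1_synthetic_prot.txt",
    "DQB1": "dqb1_synthetic_prot.txt",
}


def _data_text(name: str) -> str:
    return resources.files("hlarepeat.data").joinpath(name).read_text()


def load_packaged_store() -> AlleleStore:
    """The synthetic reference bundle shipped with the package."""
    alignments = [load_alignment(_data_text(fn), locus=locus)
                  for locus, fn in _LOCUS_FILES.items()]
    mask = load_mask_text(_data_text("mask_synthetic.tsv"))
    serology = load_serology_text(_data_text("serology_synthetic.tsv"))
    return build_store(alignments, mask, serology)


def load_mask_text(text: str):
    import io
    return load_mask(io.StringIO(text))


def load_serology_text(text: str):
    import io
    return load_serology(io.StringIO(text))


def _typing(subject_id: str, role: str, names: dict[str, list[str]]) -> HLATyping:
    return HLATyping(subject_id=subject_id, role=role,
                     alleles={lo: tuple(parse_allele(n) for n in ns)
                              for lo, ns in names.items()})


def worked_example_triad() -> Triad:
    """The DQ7 / DQ8 / DQ4 illustration triad.

    Recipient DQ7 (DQB1*03:01 homozygous), kidney donor DQ8 (DQB1*03:02),
    MSC donor DQ4 — assigned here to the DQB1*04:02 allele. No repeated
    split mismatch, yet three repeated amino-acid mismatches.
    """
    return Triad(
        patient_id="example",
        recipient=_typing("example:recipient", "recipient",
                          {"DQB1": ["DQB1*03:01", "DQB1*03:01"]}),
        kidney=_typing("example:kidney", "kidney",
                       {"DQB1": ["DQB1*03:02", "DQB1*03:02"]}),
        msc=_typing("example:msc", "msc",
                    {"DQB1": ["DQB1*04:02", "DQB1*04:02"]}),
    )


def reconstructed_55r_panel() -> tuple[SabPanel, HLATyping]:
    """A reconstructed mini-panel for the position-55 arginine inference.

    Positive beads: DQB1*06:02 (BCM 3,318) and DQB1*06:03 (BCM 2,560) — the
    quoted assay values — plus DQ4- and DQ5-group beads; negative beads are
    the recipient's own DQ2/DQ7 alleles and the remaining DQ3-group alleles.
    The recipient types DQ2/DQ7 (DQB1*02:01, DQB1*03:01). Residue 55R is
    the uniquely shared solvent-accessible mismatch of the positives.
    """
    dqa = {"DQB1*06:02": "DQA1*01:01", "DQB1*06:03": "DQA1*01:01",
           "DQB1*06:04": "DQA1*01:01", "DQB1*05:01": "DQA1*01:01",
           "DQB1*04:01": "DQA1*03:01", "DQB1*04:02": "DQA1*03:01",
           "DQB1*02:01": "DQA1*05:01", "DQB1*03:01": "DQA1*05:01",
           "DQB1*03:02": "DQA1*03:01", "DQB1*03:03": "DQA1*03:01"}
    bcm = {"DQB1*06:02": 3318, "DQB1*06:03": 2560, "DQB1*06:04": 1800,
           "DQB1*05:01": 2100, "DQB1*04:01": 1500, "DQB1*04:02": 1650,
           "DQB1*02:01": 150, "DQB1*03:01": 90, "DQB1*03:02": 240,
           "DQB1*03:03": 310}
    beads = tuple(
        Bead(bead_id=f"bead-{i+1:02d}",
             alleles=(parse_allele(b), parse_allele(dqa[b])), bcm=float(v))
        for i, (b, v) in enumerate(sorted(bcm.items()))
    )
    panel = SabPanel(sample_id="reconstructed-55R", beads=beads, timepoint=16.0)
    recipient = _typing("reconstructed:recipient", "recipient",
                        {"DQB1": ["DQB1*02:01", "DQB1*03:01"]})
    return panel, recipient
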