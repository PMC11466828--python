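"""Split-antigen and solvent-accessible amino-acid mismatch computation for
recipient/donor pairs and recipient/kidney-donor/MSC-donor triads.

Mismatch semantics
------------------
Split level: a donor split antigen is mismatched when it is absent from the
recipient's split antigens at the same locus. Counted loci are A, B, C, DR
(DRB1; DR51/52/53 from DRB3/4/5 optionally included) and DQ (DQB1).

Amino-acid level: a donor residue at a solvent-accessible position is
mismatched when no recipient allele in the comparison scope carries that
residue at that position. Class I is compared intralocus (recipient alleles
of the same locus); DR and DQB donor alleles are compared against a pooled
interlocus set of recipient class II beta chains (DRB1/3/4/5 + DQB1) by
default, switchable to intralocus. Mismatches are pooled per locus group
(class I, DR, DQB) as unique (position, residue) pairs, so a residue carried
by both donor alleles counts once.

A repeated mismatch is a recipient/kidney-donor mismatch that is also a
recipient/MSC-donor mismatch: the set intersection of the two profiles, at
either level.

Null-expression (N) alleles encode no surface protein and are excluded from
both donor contributions and the recipient matching pool. Unknown residues
never produce mismatches.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .nomenclature import AlleleName, CLASS_I_LOCI, DRB_LOCI
from .store import AlleleStore, UNKNOWN, UnknownAlleleError
from .subjects import HLATyping, Triad

SPLIT_LOCI = ("A", "B", "C", "DR", "DQ")
LOCUS_GROUPS = ("class_I", "DR", "DQB")

#: loci whose donor alleles feed each amino-acid locus group
GROUP_LOCI = {"class_I": CLASS_I_LOCI, "DR": DRB_LOCI, "DQB": ("DQB1",)}

#: pooled recipient loci for the class II interlocus comparison scope
CLASS_II_POOL = DRB_LOCI + ("DQB1",)

Scope = Literal["interlocus", "intralocus"]


@dataclass(frozen=True, order=True)
class PositionResidue:
    """A mismatched solvent-accessible residue, identified within its locus
    group by (position, residue)."""

    group: str
    position: int
    residue: str

    def __post_init__(self) -> None:
        if self.residue == UNKNOWN:
            raise ValueError("a mismatch residue must be a concrete amino acid")
        if self.position < 1:
            raise ValueError("positions are 1-based mature-protein numbering")

    def label(self) -> str:
        """Field-style label, e.g. '55R'."""
        return f"{self.position}{self.residue}"


@dataclass(frozen=True)
class MismatchProfile:
    """All mismatches of one recipient/donor pair."""

    pair_id: str
    split: dict[str, frozenset[str]]
    aa: dict[str, frozenset[PositionResidue]]

    def split_count(self, locus: str) -> int:
        return len(self.split[locus])

    def aa_count(self, group: str) -> int:
        return len(self.aa[group])


@dataclass(frozen=True)
class TriadReport:
    """Kidney, MSC and repeated mismatch sets for one patient triad."""

    patient_id: str
    kidney: MismatchProfile
    msc: MismatchProfile
    repeated_split: dict[str, frozenset[str]]
    repeated_aa: dict[str, frozenset[PositionResidue]]

    def repeated_split_count(self, locus: str) -> int:
        return len(self.repeated_split[locus])

    def repeated_aa_count(self, group: str) -> int:
        return len(self.repeated_aa[group])

    def total_repeated_aa(self) -> int:
        """Total repeated amino-acid mismatches (class I + DR + DQB)."""
        return sum(len(v) for v in self.repeated_aa.values())

    def to_dict(self) -> dict:
        def _aa(d):
            return {g: sorted([p.position, p.residue] for p in v)
                    for g, v in d.items()}

        def _split(d):
            return {k: sorted(v) for k, v in d.items()}

        return {
            "patient_id": self.patient_id,
            "kidney": {"split": _split(self.kidney.split), "aa": _aa(self.kidney.aa)},
            "msc": {"split": _split(self.msc.split), "aa": _aa(self.msc.aa)},
            "repeated": {"split": _split(self.repeated_split),
                         "aa": _aa(self.repeated_aa)},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TriadReport":
        def _aa(block):
            return {g: frozenset(PositionResidue(g, p, r) for p, r in v)
                    for g, v in block.items()}

        def _split(block):
            return {k: frozenset(v) for k, v in block.items()}

        pid = d["patient_id"]
        kidney = MismatchProfile(f"{pid}:kidney", _split(d["kidney"]["split"]),
                                 _aa(d["kidney"]["aa"]))
        msc = MismatchProfile(f"{pid}:msc", _split(d["msc"]["split"]),
                              _aa(d["msc"]["aa"]))
        return cls(pid, kidney, msc, _split(d["repeated"]["split"]),
                   _aa(d["repeated"]["aa"]))


# --------------------------------------------------------------------------
# split level
# --------------------------------------------------------------------------

def split_antigens(typing: HLATyping, store: AlleleStore, locus: str,
                   include_drb345: bool = False) -> frozenset[str]:
    """Split antigens a subject expresses at one counted locus."""
    if locus == "DR":
        alleles = list(typing.expressed_at("DRB1"))
        if include_drb345:
            for lo in ("DRB3", "DRB4", "DRB5"):
                alleles.extend(typing.expressed_at(lo))
    elif locus == "DQ":
        alleles = list(typing.expressed_at("DQB1"))
    else:
        alleles = list(typing.expressed_at(locus))
    return frozenset(store.split_antigen(a) for a in alleles)


def split_mismatches(recipient: HLATyping, donor: HLATyping,
                     store: AlleleStore,
                     include_drb345: bool = False) -> dict[str, frozenset[str]]:
    """Donor split antigens absent from the recipient, per counted locus.

    Homozygous donors contribute each antigen once (set semantics), so
    counts per locus are 0-2. Unmapped alleles raise, never drop silently.
    """
    out = {}
    for locus in SPLIT_LOCI:
        r = split_antigens(recipient, store, locus, include_drb345)
        d = split_antigens(donor, store, locus, include_drb345)
        out[locus] = frozenset(d - r)
    return out


# --------------------------------------------------------------------------
# amino-acid level
# --------------------------------------------------------------------------

def _recipient_pool(recipient: HLATyping, group: str, donor_locus: str,
                    scope: Scope) -> list[AlleleName]:
    if group == "class_I":
        return list(recipient.expressed_at(donor_locus))
    if scope == "interlocus":
        pool: list[AlleleName] = []
        for lo in CLASS_II_POOL:
            pool.extend(recipient.expressed_at(lo))
        return pool
    return list(recipient.expressed_at(donor_locus))


def aa_mismatches(recipient: HLATyping, donor: HLATyping, store: AlleleStore,
                  scope: Scope = "interlocus") -> dict[str, frozenset[PositionResidue]]:
    """Solvent-accessible amino-acid mismatches per locus group.

    For every expressed donor allele and every masked position of its locus,
    the donor residue is a mismatch iff it is concrete and no recipient
    allele in the comparison scope carries it at that position. Unknown
    residues are uninformative: a donor unknown never produces a mismatch,
    and a recipient unknown never confirms a match. Pairs are pooled per
    locus group with duplicates counted once.
    """
    out: dict[str, frozenset[PositionResidue]] = {}
    for group, loci in GROUP_LOCI.items():
        pairs: set[PositionResidue] = set()
        for locus in loci:
            donor_alleles = donor.expressed_at(locus)
            if not donor_alleles:
                continue
            mask = store.mask.for_locus(locus)
            for da in donor_alleles:
                if not store.has_sequence(da):
                    raise UnknownAlleleError(
                        f"donor allele {da} has no reference sequence")
                pool = _recipient_pool(recipient, group, locus, scope)
                pool_seqs = [store.sequence(a) for a in pool
                             if store.has_sequence(a) or _raise_missing(a)]
                dseq = store.sequence(da)
                for pos in sorted(mask):
                    r = dseq.residue_at(pos)
                    if r == UNKNOWN:
                        continue
                    if not any(ps.residue_at(pos) == r for ps in pool_seqs):
                        pairs.add(PositionResidue(group, pos, r))
        out[group] = frozenset(pairs)
    return out


def _raise_missing(allele: AlleleName) -> bool:
    raise UnknownAlleleError(f"recipient allele {allele} has no reference sequence")


# --------------------------------------------------------------------------
# pairs and triads
# --------------------------------------------------------------------------

def mismatch_profile(recipient: HLATyping, donor: HLATyping, store: AlleleStore,
                     scope: Scope = "interlocus",
                     include_drb345: bool = False) -> MismatchProfile:
    return MismatchProfile(
        pair_id=f"{recipient.subject_id}/{donor.subject_id}",
        split=split_mismatches(recipient, donor, store, include_drb345),
        aa=aa_mismatches(recipient, donor, store, scope),
    )


def repeated_mismatches(recipient: HLATyping, kidney: HLATyping,
                        msc: HLATyping, store: AlleleStore,
                        scope: Scope = "interlocus",
                        include_drb345: bool = False,
                        patient_id: str | None = None) -> TriadReport:
    """Compute both donor profiles and their intersection for one triad."""
    kp = mismatch_profile(recipient, kidney, store, scope, include_drb345)
    mp = mismatch_profile(recipient, msc, store, scope, include_drb345)
    return TriadReport(
        patient_id=patient_id or recipient.subject_id.split(":")[0],
        kidney=kp,
        msc=mp,
        repeated_split={lo: kp.split[lo] & mp.split[lo] for lo in SPLIT_LOCI},
        repeated_aa={g: kp.aa[g] & mp.aa[g] for g in LOCUS_GROUPS},
    )


def analyze_triad(triad: Triad, store: AlleleStore,
                  scope: Scope = "interlocus",
                  include_drb345: bool = False) -> TriadReport:
    return repeated_mismatches(triad.recipient, triad.kidney, triad.msc, store,
                               scope, include_drb345, patient_id=triad.patient_id)


def triad_table(reports: Iterable[TriadReport]) -> pd.DataFrame:
    """Cohort mismatch table: one kidney/MSC/repeated row-block per patient,
    with split counts (A, B, C, DR, DQ) and amino-acid counts per group."""
    reports = list(reports)
    if not reports:
        raise ValueError("triad_table requires at least one report")
    rows = []
    for rep in reports:
        for name, split, aa in (
            ("kidney", rep.kidney.split, rep.kidney.aa),
            ("msc", rep.msc.split, rep.msc.aa),
            ("repeated", rep.repeated_split, rep.repeated_aa),
        ):
            row = {"patient_id": rep.patient_id, "comparison": name}
            for lo in SPLIT_LOCI:
                row[lo] = len(split[lo])
            for g in LOCUS_GROUPS:
                row[f"aa_{g}"] = len(aa[g])
            rows.append(row)
    return pd.DataFrame(rows)


def write_reports_json(reports: Iterable[TriadReport], path,
                       provenance: dict | None = None) -> None:
    payload = {"provenance": provenance or {},
               "reports": [r.to_dict() for r in reports]}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_reports_json(path) -> list[TriadReport]:
    payload = json.loads(Path(path).read_text())
    return [TriadReport.from_dict(d) for d in payload["reports"]]
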