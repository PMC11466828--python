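"""Single-antigen bead (SAB) panel interpretation.

Each Luminex bead carries one HLA protein (class I) or a beta/alpha pair
(class II, e.g. DQB1*06:04 with DQA1*01:01). Beads with a
background-corrected MFI (BCM) at or above the positivity threshold
(default 1,000) are positive. Positive beads are assigned against the triad
typings by second-field allele identity — never by serologic similarity,
which is known to misassign antibodies when the bead allele merely shares a
split antigen with the donor allele.

Whole-panel self-reactivity: when a bead carrying one of the recipient's own
alleles is positive, the assay is flagged as background and donor-specific
assignments are suppressed.

Candidate target residues: the antibody's footprint is localized by finding
solvent-accessible (position, residue) pairs present on every positive
bead's relevant allele and absent from the recipient — and, in the strict
reading, absent from every negative bead as well ("uniquely shared by all
reactive beads").
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .mismatch import GROUP_LOCI, PositionResidue, Scope, _recipient_pool
from .nomenclature import AlleleName, parse_allele
from .store import AlleleStore, UNKNOWN
from .subjects import HLATyping

DEFAULT_THRESHOLD = 1000.0

ASSIGNMENTS = ("self", "shared", "kidney-donor", "msc-donor", "third-party")


@dataclass(frozen=True)
class Bead:
    bead_id: str
    alleles: tuple[AlleleName, ...]
    bcm: float

    def __post_init__(self) -> None:
        if self.bcm < 0:
            raise ValueError(f"bead {self.bead_id}: BCM must be >= 0")
        if not 1 <= len(self.alleles) <= 2:
            raise ValueError(f"bead {self.bead_id}: 1 or 2 alleles required")

    def allele_for_group(self, group: str) -> AlleleName | None:
        """The bead allele relevant to a locus group (the beta chain for
        class II); None when the bead carries no allele of that group."""
        for a in self.alleles:
            if a.locus in GROUP_LOCI[group]:
                return a
        return None

    @property
    def primary(self) -> AlleleName:
        """Class I allele, or the class II beta chain; drives DSA assignment."""
        for a in self.alleles:
            if a.locus not in ("DQA1", "DPA1"):
                return a
        return self.alleles[0]


@dataclass(frozen=True)
class SabPanel:
    sample_id: str
    beads: tuple[Bead, ...]
    timepoint: float | None = None
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("positivity threshold must be > 0")
        ids = [b.bead_id for b in self.beads]
        if len(set(ids)) != len(ids):
            raise ValueError(f"panel {self.sample_id}: duplicate bead ids")


@dataclass
class DsaCall:
    sample_id: str
    positives: list[Bead]
    assignments: dict[str, str]
    background: bool
    background_reason: str | None
    candidates_strict: list[PositionResidue] = field(default_factory=list)
    candidates_lenient: list[PositionResidue] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "positives": [{"bead_id": b.bead_id,
                           "alleles": [str(a) for a in b.alleles],
                           "bcm": b.bcm} for b in self.positives],
            "assignments": self.assignments,
            "background": self.background,
            "background_reason": self.background_reason,
            "candidates_strict": [[c.position, c.residue]
                                  for c in self.candidates_strict],
            "candidates_lenient": [[c.position, c.residue]
                                   for c in self.candidates_lenient],
        }


def call_positivity(panel: SabPanel) -> tuple[list[Bead], list[Bead]]:
    """Partition beads into (positives, negatives) at the panel threshold.

    A bead is positive iff its BCM is at or above the threshold; the
    partition is exhaustive and disjoint.
    """
    pos = [b for b in panel.beads if b.bcm >= panel.threshold]
    neg = [b for b in panel.beads if b.bcm < panel.threshold]
    return pos, neg


def flag_self_background(panel: SabPanel, recipient: HLATyping,
                         mode: str = "strict",
                         ratio: float = 0.7) -> tuple[bool, str | None]:
    """Flag the panel as background when a self-allele bead is positive.

    ``mode='strict'`` (default): any positive bead carrying a recipient
    allele raises the flag. ``mode='ratio'``: the flag is raised only when
    the strongest positive self bead reaches ``ratio`` times the maximum
    positive BCM, the magnitude-comparison reading.
    """
    positives, _ = call_positivity(panel)
    self_pos = [b for b in positives
                if any(recipient.carries(a) for a in b.alleles)]
    if not self_pos:
        return False, None
    if mode == "ratio":
        max_bcm = max(b.bcm for b in positives)
        self_pos = [b for b in self_pos if b.bcm >= ratio * max_bcm]
        if not self_pos:
            return False, None
    worst = max(self_pos, key=lambda b: b.bcm)
    return True, (f"self-allele bead {worst.bead_id} "
                  f"({'/'.join(str(a) for a in worst.alleles)}) positive "
                  f"with BCM {worst.bcm:g}")


def assign_dsa(panel: SabPanel, recipient: HLATyping, kidney: HLATyping,
               msc: HLATyping, background_mode: str = "strict") -> DsaCall:
    """Label every positive bead by second-field allele identity.

    self > shared (mismatched allele carried by both donors) > kidney-donor
    > msc-donor > third-party. When the self-background flag is raised the
    assignments are still reported, but the call is marked background and
    must not be read as DSA.
    """
    positives, _ = call_positivity(panel)
    flagged, reason = flag_self_background(panel, recipient, mode=background_mode)
    assignments: dict[str, str] = {}
    for bead in positives:
        a = bead.primary
        if recipient.carries(a):
            label = "self"
        else:
            in_kidney = kidney.carries(a)
            in_msc = msc.carries(a)
            if in_kidney and in_msc:
                label = "shared"
            elif in_kidney:
                label = "kidney-donor"
            elif in_msc:
                label = "msc-donor"
            else:
                label = "third-party"
        assignments[bead.bead_id] = label
    return DsaCall(sample_id=panel.sample_id, positives=positives,
                   assignments=assignments, background=flagged,
                   background_reason=reason)


def candidate_residues(panel: SabPanel, recipient: HLATyping,
                       store: AlleleStore, group: str,
                       scope: Scope = "interlocus",
                       ) -> tuple[list[PositionResidue], list[PositionResidue]]:
    """Infer candidate antibody-target residues from the reactivity pattern.

    Returns ``(strict, lenient)`` lists of masked (position, residue) pairs:

    * lenient — present on every positive bead's group allele and absent
      from every recipient allele in the comparison scope;
    * strict — lenient pairs that are additionally absent from every
      negative bead's group allele (the pattern "uniquely shared by all
      reactive beads").

    Both lists are ranked by the number of negative beads a pair excludes,
    ties broken by (position, residue); empty when no bead in the group is
    positive.
    """
    positives, negatives = call_positivity(panel)
    pos_alleles = [b.allele_for_group(group) for b in positives]
    pos_alleles = [a for a in pos_alleles if a is not None]
    if not pos_alleles:
        return [], []
    neg_alleles = [b.allele_for_group(group) for b in negatives]
    neg_alleles = [a for a in neg_alleles if a is not None]

    pool = _recipient_pool(recipient, group, pos_alleles[0].locus, scope)
    lenient: list[tuple[int, PositionResidue]] = []
    strict: list[tuple[int, PositionResidue]] = []
    mask = sorted(set().union(*(store.mask.for_locus(lo)
                                for lo in GROUP_LOCI[group]
                                if lo in store.mask.positions)))
    for pos in mask:
        shared = {store.residue_at(a, pos) for a in pos_alleles}
        if len(shared) != 1:
            continue
        res = shared.pop()
        if res == UNKNOWN:
            continue
        if any(store.residue_at(ra, pos) == res for ra in pool):
            continue
        pr = PositionResidue(group, pos, res)
        excluded = sum(1 for na in neg_alleles
                       if store.residue_at(na, pos) != res)
        lenient.append((excluded, pr))
        if excluded == len(neg_alleles):
            strict.append((excluded, pr))

    def _rank(items):
        return [pr for _, pr in sorted(items,
                                       key=lambda t: (-t[0], t[1].position,
                                                      t[1].residue))]

    return _rank(strict), _rank(lenient)


def analyze_panel(panel: SabPanel, recipient: HLATyping, kidney: HLATyping,
                  msc: HLATyping, store: AlleleStore,
                  groups: tuple[str, ...] = ("class_I", "DR", "DQB"),
                  scope: Scope = "interlocus",
                  background_mode: str = "strict") -> DsaCall:
    """Full panel workup: positivity, background flag, assignment, candidates."""
    call = assign_dsa(panel, recipient, kidney, msc, background_mode)
    strict: list[PositionResidue] = []
    lenient: list[PositionResidue] = []
    for g in groups:
        s, l = candidate_residues(panel, recipient, store, g, scope)
        strict.extend(s)
        lenient.extend(l)
    call.candidates_strict = strict
    call.candidates_lenient = lenient
    return call


# --------------------------------------------------------------------------
# IO
# --------------------------------------------------------------------------

def read_panels_csv(path, threshold: float = DEFAULT_THRESHOLD) -> list[SabPanel]:
    """Read bead panels from CSV with columns sample_id, timepoint, bead_id,
    allele1, allele2, bcm (allele2 may be empty)."""
    df = pd.read_csv(path, dtype=str, comment="#").fillna("")
    panels = []
    for (sid,), block in df.groupby(["sample_id"], sort=True):
        beads = []
        timepoint = None
        for _, row in block.iterrows():
            alleles = [parse_allele(row["allele1"])]
            if row.get("allele2", ""):
                alleles.append(parse_allele(row["allele2"]))
            beads.append(Bead(bead_id=row["bead_id"], alleles=tuple(alleles),
                              bcm=float(row["bcm"])))
            if row.get("timepoint", ""):
                timepoint = float(row["timepoint"])
        panels.append(SabPanel(sample_id=str(sid), beads=tuple(beads),
                               timepoint=timepoint, threshold=threshold))
    return panels


def bead_residue_matrix(panel: SabPanel, store: AlleleStore,
                        group: str) -> pd.DataFrame:
    """Bead-by-position residue matrix for a locus group (one row per bead
    carrying a group allele, one column per masked position), for
    reactivity-pattern displays alongside BCM and positivity."""
    rows = {}
    meta = {}
    mask = sorted(set().union(*(store.mask.for_locus(lo)
                                for lo in GROUP_LOCI[group]
                                if lo in store.mask.positions)))
    for bead in panel.beads:
        a = bead.allele_for_group(group)
        if a is None:
            continue
        rows[bead.bead_id] = {p: store.residue_at(a, p) for p in mask}
        meta[bead.bead_id] = {"allele": str(a), "bcm": bead.bcm,
                              "positive": bead.bcm >= panel.threshold}
    df = pd.DataFrame.from_dict(rows, orient="index")
    info = pd.DataFrame.from_dict(meta, orient="index")
    return pd.concat([info, df], axis=1)


def write_call_json(call: DsaCall, path) -> None:
    import json
    Path(path).write_text(json.dumps(call.to_dict(), indent=2, sort_keys=True)
                          + "\n")
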