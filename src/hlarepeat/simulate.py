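"""Synthetic triad cohorts and single-antigen bead panels with known ground
truth.

The generator emulates the two study designs: an unselected cohort (MSC
donors drawn blind, the Liège design) and a selected cohort in which MSC
candidates sharing any split-antigen mismatch with the kidney donor at
HLA-A, -B, -DR or -DQ are rejected (the Neptune design). When no candidate
in a patient's pool qualifies, the least-violating candidate is accepted and
flagged, mirroring the one accepted DQ repeat in the selected cohort.

Ground-truth triad reports are computed by the brute-force oracle
(:mod:`hlarepeat.oracle`), never by the mismatch engine under test.

Bead panels draw BCM values from log-normal noise around a background median
of 100; an implanted antibody raises every bead carrying the target residue
to a median of 5,000 — an order of magnitude above the 1,000 positivity
cutoff, consistent with the BCM magnitudes the assays report. A
self-background scenario instead raises one recipient-allele bead above the
cutoff. All randomness flows from explicit seeds.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from . import oracle
from .mismatch import GROUP_LOCI, MismatchProfile, PositionResidue, \
    TriadReport
from .nomenclature import AlleleName, parse_allele
from .sab import Bead, SabPanel
from .store import AlleleStore
from .subjects import HLATyping, Triad

POLICY_LOCI = ("A", "B", "DR", "DQ")
SAMPLED_LOCI = ("A", "B", "C", "DRB1", "DQB1")

#: beta -> alpha pairing used to compose class II beads
DQA_PAIRING = {
    "DQB1*02:01": "DQA1*05:01", "DQB1*02:02": "DQA1*05:01",
    "DQB1*03:01": "DQA1*05:01", "DQB1*03:02": "DQA1*03:01",
    "DQB1*03:03": "DQA1*03:01", "DQB1*04:01": "DQA1*03:01",
    "DQB1*04:02": "DQA1*03:01", "DQB1*05:01": "DQA1*01:01",
    "DQB1*06:02": "DQA1*01:01", "DQB1*06:03": "DQA1*01:01",
    "DQB1*06:04": "DQA1*01:01",
}


class InvalidScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class AllelePool:
    """Sampling pool: alleles and frequencies per locus, backed by a store."""

    alleles: dict[str, tuple[AlleleName, ...]]
    frequencies: dict[str, tuple[float, ...]]
    store: AlleleStore

    def __post_init__(self) -> None:
        for locus, alls in self.alleles.items():
            if not alls:
                raise ValueError(f"empty allele pool for locus {locus}")
            freqs = self.frequencies[locus]
            if len(freqs) != len(alls) or any(f < 0 for f in freqs):
                raise ValueError(f"bad frequencies for locus {locus}")
            if abs(sum(freqs) - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {locus} must sum to 1")
            for a in alls:
                self.store.sequence(a)           # must have a sequence
                self.store.split_antigen(a)      # and a serology entry

    @classmethod
    def from_store(cls, store: AlleleStore,
                   loci: tuple[str, ...] = SAMPLED_LOCI) -> "AllelePool":
        """Uniform-frequency pool over the store's alleles at ``loci``."""
        alleles = {}
        freqs = {}
        for locus in loci:
            alls = tuple(sorted((a for a in store.sequences if a.locus == locus)))
            alleles[locus] = alls
            freqs[locus] = tuple([1.0 / len(alls)] * len(alls))
        return cls(alleles=alleles, frequencies=freqs, store=store)


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 10
    selection_policy: Literal["none", "avoid-repeated-split"] = "none"
    msc_pool_size: int = 10
    noise_sigma: float = 0.35
    background_bcm: float = 100.0
    implant_bcm: float = 5000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.selection_policy not in ("none", "avoid-repeated-split"):
            raise ValueError(f"unknown policy {self.selection_policy!r}")


@dataclass
class SimulatedCohort:
    triads: list[Triad]
    reports: list[TriadReport]       # ground truth from the brute-force oracle
    flagged: set[str] = field(default_factory=set)  # accepted policy violations


def _sample_typing(pool: AllelePool, rng: np.random.Generator,
                   subject_id: str, role: str) -> HLATyping:
    alleles = {}
    for locus in pool.alleles:
        alls = pool.alleles[locus]
        idx = rng.choice(len(alls), size=2, replace=True,
                         p=np.asarray(pool.frequencies[locus]))
        alleles[locus] = (alls[idx[0]], alls[idx[1]])
    return HLATyping(subject_id=subject_id, role=role, alleles=alleles)


def _oracle_report(patient_id: str, recipient: HLATyping, kidney: HLATyping,
                   msc: HLATyping, store: AlleleStore) -> TriadReport:
    res = oracle.brute_triad(recipient, kidney, msc, store)
    return TriadReport(
        patient_id=patient_id,
        kidney=MismatchProfile(f"{patient_id}:kidney", res["kidney_split"],
                               res["kidney_aa"]),
        msc=MismatchProfile(f"{patient_id}:msc", res["msc_split"],
                            res["msc_aa"]),
        repeated_split=res["repeated_split"],
        repeated_aa=res["repeated_aa"],
    )


def _split_violations(recipient: HLATyping, kidney_mm: dict, msc: HLATyping,
                      store: AlleleStore) -> int:
    msc_mm = oracle.brute_split_mismatches(recipient, msc, store)
    return sum(len(kidney_mm[lo] & msc_mm[lo]) for lo in POLICY_LOCI)


def simulate_triads(pool: AllelePool, config: SimulationConfig) -> SimulatedCohort:
    """Sample a cohort of recipient/kidney/MSC triads under a selection policy.

    Recipients and kidney donors are drawn independently per locus. Each
    patient gets ``msc_pool_size`` candidate MSC donors; under the
    avoid-repeated-split policy the first candidate with no repeated
    split-antigen mismatch at A, B, DR, DQ is chosen, and if none qualifies
    the least-violating candidate is accepted and flagged. Fixed seeds give
    byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    store = pool.store
    triads: list[Triad] = []
    reports: list[TriadReport] = []
    flagged: set[str] = set()
    for i in range(config.n_patients):
        pid = f"S{i + 1}"
        recipient = _sample_typing(pool, rng, f"{pid}:recipient", "recipient")
        kidney = _sample_typing(pool, rng, f"{pid}:kidney", "kidney")
        candidates = [_sample_typing(pool, rng, f"{pid}:msc", "msc")
                      for _ in range(config.msc_pool_size)]
        if config.selection_policy == "none":
            msc = candidates[0]
        else:
            kidney_mm = oracle.brute_split_mismatches(recipient, kidney, store)
            scored = [(_split_violations(recipient, kidney_mm, c, store), j)
                      for j, c in enumerate(candidates)]
            best_score, best_j = min(scored)
            msc = candidates[best_j]
            if best_score > 0:
                flagged.add(pid)
        triads.append(Triad(patient_id=pid, recipient=recipient,
                            kidney=kidney, msc=msc))
        reports.append(_oracle_report(pid, recipient, kidney, msc, store))
    return SimulatedCohort(triads=triads, reports=reports, flagged=flagged)


# --------------------------------------------------------------------------
# bead panels
# --------------------------------------------------------------------------

def _panel_beads(pool: AllelePool) -> list[tuple[str, tuple[AlleleName, ...]]]:
    beads = []
    i = 0
    for locus in pool.alleles:
        if locus in ("DQA1", "DPA1"):
            continue
        for a in pool.alleles[locus]:
            i += 1
            alleles: tuple[AlleleName, ...] = (a,)
            if locus == "DQB1":
                alpha = DQA_PAIRING.get(str(a))
                if alpha is not None:
                    alleles = (a, parse_allele(alpha))
            beads.append((f"bead-{i:03d}", alleles))
    return beads


def choose_implant(triad: Triad, store: AlleleStore, group: str,
                   seed: int) -> PositionResidue:
    """Pick a kidney-donor mismatched residue to implant as antibody target."""
    mm = oracle.brute_aa_mismatches(triad.recipient, triad.kidney, store)
    options = sorted(mm[group])
    if not options:
        raise InvalidScenarioError(
            f"triad {triad.patient_id}: no {group} mismatch to implant")
    rng = np.random.default_rng(seed)
    return options[rng.integers(len(options))]


def simulate_sab(triad: Triad, scenario: str, pool: AllelePool, seed: int,
                 implant: PositionResidue | None = None,
                 config: SimulationConfig = SimulationConfig()) -> tuple[SabPanel, dict]:
    """Generate one bead panel for a triad under a DSA scenario.

    ``scenario``: ``'none'`` (background only), ``'implant'`` (antibody
    against ``implant``, which must be absent from the recipient), or
    ``'self-background'`` (one recipient-allele bead raised above cutoff).
    Returns the panel and a ground-truth record (intended positives, the
    implanted residue, intended per-bead assignment).
    """
    store = pool.store
    rng = np.random.default_rng(seed)
    beads_spec = _panel_beads(pool)

    carriers: set[str] = set()
    if scenario == "implant":
        if implant is None:
            raise InvalidScenarioError("implant scenario requires a residue")
        # must be a true mismatch: absent from every recipient allele of the group
        for locus in GROUP_LOCI[implant.group]:
            for ra in triad.recipient.expressed_at(locus):
                if store.residue_at(ra, implant.position) == implant.residue:
                    raise InvalidScenarioError(
                        f"implant {implant.label()} present on recipient "
                        f"allele {ra}")
        for bead_id, alleles in beads_spec:
            for a in alleles:
                if a.locus in GROUP_LOCI[implant.group] and \
                        store.residue_at(a, implant.position) == implant.residue:
                    carriers.add(bead_id)
    elif scenario == "self-background":
        recip_alleles = {str(a.two_field())
                         for alls in triad.recipient.alleles.values()
                         for a in alls}
        self_beads = [bid for bid, alleles in beads_spec
                      if str(alleles[0].two_field()) in recip_alleles]
        if not self_beads:
            raise InvalidScenarioError("no recipient-allele bead in the panel")
        carriers = {self_beads[rng.integers(len(self_beads))]}
    elif scenario != "none":
        raise InvalidScenarioError(f"unknown scenario {scenario!r}")

    beads = []
    for bead_id, alleles in beads_spec:
        noise = float(np.exp(config.noise_sigma * rng.standard_normal()))
        if bead_id in carriers and scenario == "implant":
            bcm = config.implant_bcm * noise
        elif bead_id in carriers:
            bcm = 2000.0 * float(np.exp(0.1 * rng.standard_normal()))
        else:
            bcm = config.background_bcm * noise
        beads.append(Bead(bead_id=bead_id, alleles=alleles, bcm=bcm))
    panel = SabPanel(sample_id=f"{triad.patient_id}:{scenario}",
                     beads=tuple(beads))

    kidney_alleles = {str(a.two_field())
                      for alls in triad.kidney.alleles.values() for a in alls}
    msc_alleles = {str(a.two_field())
                   for alls in triad.msc.alleles.values() for a in alls}
    recip_alleles = {str(a.two_field())
                     for alls in triad.recipient.alleles.values() for a in alls}
    intended = {}
    for bead_id, alleles in beads_spec:
        key = str(alleles[0].two_field())
        if key in recip_alleles:
            intended[bead_id] = "self"
        elif key in kidney_alleles and key in msc_alleles:
            intended[bead_id] = "shared"
        elif key in kidney_alleles:
            intended[bead_id] = "kidney-donor"
        elif key in msc_alleles:
            intended[bead_id] = "msc-donor"
        else:
            intended[bead_id] = "third-party"
    truth = {
        "scenario": scenario,
        "implant": [implant.group, implant.position, implant.residue]
        if implant is not None else None,
        "intended_positive": sorted(carriers),
        "intended_assignment": intended,
    }
    return panel, truth
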