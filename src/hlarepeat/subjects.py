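"""Subject HLA typings (recipient, kidney donor, MSC donor) and their CSV IO.

A typing records one or two alleles per locus at second-field resolution.
DRB3/4/5 may be absent entirely (no gene on either haplotype); homozygosity
is written as two identical alleles.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .nomenclature import AlleleName, parse_allele, SUPPORTED_LOCI

ROLES = ("recipient", "kidney", "msc")


@dataclass(frozen=True)
class HLATyping:
    subject_id: str
    role: str
    alleles: dict[str, tuple[AlleleName, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        for locus, alls in self.alleles.items():
            if locus not in SUPPORTED_LOCI:
                raise ValueError(f"unsupported locus {locus!r}")
            if not 1 <= len(alls) <= 2:
                raise ValueError(f"{self.subject_id} {locus}: 1 or 2 alleles required")
            for a in alls:
                if a.locus != locus:
                    raise ValueError(f"allele {a} filed under locus {locus}")

    def at(self, locus: str) -> tuple[AlleleName, ...]:
        """Alleles at a locus; empty tuple when the locus is absent."""
        return self.alleles.get(locus, ())

    def expressed_at(self, locus: str) -> tuple[AlleleName, ...]:
        """Alleles at a locus excluding null-expression (N-suffix) variants."""
        return tuple(a for a in self.at(locus) if not a.is_null)

    def carries(self, allele: AlleleName) -> bool:
        key = allele.two_field()
        return any(a.two_field() == key for a in self.at(allele.locus))


@dataclass(frozen=True)
class Triad:
    """One patient: recipient, kidney donor and MSC donor typings."""

    patient_id: str
    recipient: HLATyping
    kidney: HLATyping
    msc: HLATyping


def read_typings_csv(path) -> list[Triad]:
    """Read triads from a typing CSV.

    Columns: ``patient_id, role, locus, allele1, allele2`` with role in
    recipient/kidney/msc; allele2 may be empty (hemizygous/single allele).
    Malformed alleles raise with the offending file row.
    """
    df = pd.read_csv(path, dtype=str, comment="#").fillna("")
    required = {"patient_id", "role", "locus", "allele1"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"typing CSV missing columns: {sorted(missing)}")
    triads = []
    for pid, block in df.groupby("patient_id", sort=True):
        typings: dict[str, HLATyping] = {}
        for role, rows in block.groupby("role"):
            alleles: dict[str, tuple[AlleleName, ...]] = {}
            for idx, row in rows.iterrows():
                names = [row["allele1"]]
                if row.get("allele2", ""):
                    names.append(row["allele2"])
                try:
                    parsed = tuple(parse_allele(n) for n in names)
                except ValueError as exc:
                    raise ValueError(f"row {idx + 2}: {exc}") from exc
                alleles[row["locus"]] = parsed
            typings[role] = HLATyping(subject_id=f"{pid}:{role}", role=role,
                                      alleles=alleles)
        for role in ROLES:
            if role not in typings:
                raise ValueError(f"patient {pid}: missing {role} typing")
        triads.append(Triad(patient_id=str(pid), recipient=typings["recipient"],
                            kidney=typings["kidney"], msc=typings["msc"]))
    return triads


def write_typings_csv(triads: list[Triad], path) -> None:
    rows = []
    for t in triads:
        for typing in (t.recipient, t.kidney, t.msc):
            for locus in sorted(typing.alleles):
                alls = typing.alleles[locus]
                rows.append({
                    "patient_id": t.patient_id,
                    "role": typing.role,
                    "locus": locus,
                    "allele1": str(alls[0]),
                    "allele2": str(alls[1]) if len(alls) > 1 else "",
                })
    pd.DataFrame(rows).to_csv(Path(path), index=False)
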