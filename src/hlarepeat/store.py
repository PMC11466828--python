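"""Reference data service: aligned HLA protein sequences, the
solvent-accessibility mask, and the allele-to-split-antigen serology map.

Positions use mature-protein numbering, 1-based (leader peptide excluded),
the convention of IMGT/HLA protein alignments and of residue labels such as
"55R" (arginine at DQ beta position 55). Residues that the source alignment
does not resolve are stored as the :data:`UNKNOWN` sentinel and are treated
conservatively everywhere downstream: an unknown residue never produces a
mismatch.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .nomenclature import AlleleName, parse_allele

#: Sentinel residue for positions the source alignment does not resolve.
UNKNOWN = "X"

_VALID_RESIDUES = set("ARNDCQEGHILKMFPSTWYV")


class ReferenceLoadError(ValueError):
    """Raised when an alignment, mask or serology file is malformed."""


class UnknownAlleleError(KeyError):
    """Raised on lookups for alleles absent from the store."""


class UnmappedAlleleError(KeyError):
    """Raised when an allele has no serologic split-antigen assignment."""


@dataclass(frozen=True)
class AlleleSequence:
    """One allele's aligned residues, keyed by mature-protein position."""

    allele: AlleleName
    residues: Mapping[int, str]

    def residue_at(self, position: int) -> str:
        return self.residues.get(position, UNKNOWN)


@dataclass(frozen=True)
class AccessibilityMask:
    """Solvent-accessible positions per locus, with a data version string.

    Only masked (surface-exposed, antibody-reachable) positions enter
    mismatch analysis; buried polymorphisms are ignored.
    """

    positions: Mapping[str, frozenset[int]]
    version: str = "unversioned"

    def for_locus(self, locus: str) -> frozenset[int]:
        try:
            return self.positions[locus]
        except KeyError:
            raise ReferenceLoadError(f"no accessibility mask for locus {locus}")


@dataclass(frozen=True)
class SerologyMap:
    """Two-field allele -> WHO split-antigen label (broad parent optional)."""

    split: Mapping[AlleleName, str]
    broad: Mapping[AlleleName, str] = field(default_factory=dict)
    version: str = "unversioned"

    def split_of(self, allele: AlleleName) -> str:
        key = allele.two_field()
        try:
            return self.split[key]
        except KeyError:
            raise UnmappedAlleleError(
                f"allele {allele} has no split-antigen mapping"
            )


@dataclass
class AlleleStore:
    """Indexed reference bundle served to the mismatch and bead modules."""

    sequences: dict[AlleleName, AlleleSequence]
    mask: AccessibilityMask
    serology: SerologyMap

    def __post_init__(self) -> None:
        # alleles mapped in serology but lacking sequences are flagged up front
        self.unsequenced = sorted(
            str(a) for a in self.serology.split if a not in self.sequences
        )

    def has_sequence(self, allele: AlleleName) -> bool:
        return allele.two_field() in self.sequences

    def sequence(self, allele: AlleleName) -> AlleleSequence:
        try:
            return self.sequences[allele.two_field()]
        except KeyError:
            raise UnknownAlleleError(f"no sequence for allele {allele}")

    def residue_at(self, allele: AlleleName, position: int) -> str:
        """Residue of ``allele`` at a mature-protein position (or UNKNOWN)."""
        return self.sequence(allele).residue_at(position)

    def split_antigen(self, allele: AlleleName) -> str:
        """WHO split-antigen designation of a two-field allele."""
        return self.serology.split_of(allele)

    def loci(self) -> set[str]:
        return {a.locus for a in self.sequences}


# --------------------------------------------------------------------------
# loaders
# --------------------------------------------------------------------------

def _expand_line(encoded: str, reference: str, lineno: int) -> str:
    if len(encoded) != len(reference):
        raise ReferenceLoadError(
            f"line {lineno}: sequence length {len(encoded)} != reference "
            f"length {len(reference)}"
        )
    out = []
    for i, c in enumerate(encoded):
        if c == "-":
            out.append(reference[i])
        elif c in ("*", "."):
            out.append(UNKNOWN)
        elif c in _VALID_RESIDUES:
            out.append(c)
        else:
            raise ReferenceLoadError(f"line {lineno}: invalid residue {c!r}")
    return "".join(out)


def load_alignment(source, locus: str | None = None,
                   first_position: int = 1) -> list[AlleleSequence]:
    """Load a protein multiple alignment in the reference-plus-dashes dialect.

    The first allele line carries the full reference sequence; subsequent
    lines use ``-`` for identity with the reference, ``*`` or ``.`` for
    unresolved residues, and plain letters for substitutions. ``#`` lines are
    comments. Positions are numbered from ``first_position`` (mature-protein
    position 1 by default).

    Parameters
    ----------
    source
        Path, file object, or alignment text.
    locus
        When given, every allele line must belong to this locus.
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str):
        text = Path(source).read_text() \
            if "\n" not in source and Path(source).is_file() else source
    else:
        text = source.read()

    reference: str | None = None
    out: list[AlleleSequence] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ReferenceLoadError(f"line {lineno}: expected 'allele sequence'")
        name_str, enc = parts
        try:
            allele = parse_allele(name_str)
        except ValueError as exc:
            raise ReferenceLoadError(f"line {lineno}: {exc}") from exc
        if locus is not None and allele.locus != locus:
            raise ReferenceLoadError(
                f"line {lineno}: allele {allele} does not belong to locus {locus}"
            )
        if reference is None:
            if any(c not in _VALID_RESIDUES and c not in "*." for c in enc):
                raise ReferenceLoadError(
                    f"line {lineno}: reference sequence contains invalid residues"
                )
            reference = enc.replace("*", UNKNOWN).replace(".", UNKNOWN)
            expanded = reference
        else:
            expanded = _expand_line(enc, reference, lineno)
        residues = {first_position + i: c for i, c in enumerate(expanded)}
        out.append(AlleleSequence(allele=allele, residues=residues))
    if not out:
        raise ReferenceLoadError("alignment contains no allele lines")
    return out


def load_fasta_alignment(source, locus: str | None = None,
                         first_position: int = 1) -> list[AlleleSequence]:
    """Load an aligned per-locus FASTA (equal-length records, headers = allele
    names); ``X``, ``*`` and ``.`` become UNKNOWN."""
    from Bio import SeqIO

    if isinstance(source, (str, Path)) and "\n" not in str(source):
        handle = open(source)
    elif isinstance(source, str):
        handle = io.StringIO(source)
    else:
        handle = source
    records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise ReferenceLoadError("FASTA contains no records")
    length = len(records[0].seq)
    out = []
    for rec in records:
        if len(rec.seq) != length:
            raise ReferenceLoadError(
                f"record {rec.id}: length {len(rec.seq)} != {length}"
            )
        allele = parse_allele(rec.id)
        if locus is not None and allele.locus != locus:
            raise ReferenceLoadError(f"record {rec.id}: not locus {locus}")
        residues = {}
        for i, c in enumerate(str(rec.seq).upper()):
            residues[first_position + i] = c if c in _VALID_RESIDUES else UNKNOWN
        out.append(AlleleSequence(allele=allele, residues=residues))
    return out


def _read_versioned_tsv(path) -> tuple[list[str], str]:
    """Return non-comment lines and the '# version:' string of a data TSV."""
    text = Path(path).read_text() if isinstance(path, (str, Path)) else path.read()
    version = "unversioned"
    lines = []
    for raw in text.splitlines():
        if raw.startswith("#"):
            if "version:" in raw:
                version = raw.split("version:", 1)[1].strip()
            continue
        if raw.strip():
            lines.append(raw)
    return lines, version


def load_mask(path) -> AccessibilityMask:
    """Load the solvent-accessibility mask TSV (columns: locus, positions)."""
    lines, version = _read_versioned_tsv(path)
    positions: dict[str, frozenset[int]] = {}
    for line in lines:
        cols = line.split("\t")
        if cols[0] == "locus":
            continue
        if len(cols) != 2:
            raise ReferenceLoadError(f"mask line {line!r}: expected 2 columns")
        locus, pos = cols
        vals = frozenset(int(p) for p in pos.split(",") if p)
        if not vals:
            raise ReferenceLoadError(f"mask for locus {locus} is empty")
        positions[locus] = vals
    return AccessibilityMask(positions=positions, version=version)


def load_serology(path) -> SerologyMap:
    """Load the allele->split TSV (columns: allele, split, broad)."""
    lines, version = _read_versioned_tsv(path)
    split: dict[AlleleName, str] = {}
    broad: dict[AlleleName, str] = {}
    for line in lines:
        cols = line.split("\t")
        if cols[0] == "allele":
            continue
        if len(cols) < 2:
            raise ReferenceLoadError(f"serology line {line!r}: expected >=2 columns")
        allele = parse_allele(cols[0]).two_field()
        split[allele] = cols[1]
        if len(cols) > 2 and cols[2]:
            broad[allele] = cols[2]
    return SerologyMap(split=split, broad=broad, version=version)


def build_store(alignments: Iterable[list[AlleleSequence]],
                mask: AccessibilityMask, serology: SerologyMap) -> AlleleStore:
    sequences: dict[AlleleName, AlleleSequence] = {}
    for group in alignments:
        for seq in group:
            sequences[seq.allele.two_field()] = seq
    return AlleleStore(sequences=sequences, mask=mask, serology=serology)
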