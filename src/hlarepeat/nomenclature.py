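"""Two-field HLA allele nomenclature: parsing, formatting, expression suffixes.

Allele names follow WHO nomenclature, e.g. ``DQB1*06:02`` (locus, ``*``,
colon-separated numeric fields). Names are kept at the resolution given;
a minimum of two fields (allele group and specific protein) is required.
Expression-variant suffixes (N = null, L, S, Q, ...) are retained; null
alleles encode no surface protein and are excluded from mismatch analysis.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

SUPPORTED_LOCI = (
    "A", "B", "C",
    "DRB1", "DRB3", "DRB4", "DRB5",
    "DQA1", "DQB1", "DPA1", "DPB1",
)

CLASS_I_LOCI = ("A", "B", "C")
DRB_LOCI = ("DRB1", "DRB3", "DRB4", "DRB5")

_ALLELE_RE = re.compile(
    r"^(?P<locus>[A-Z0-9]+)\*(?P<fields>\d+(?::\d+)+)(?P<suffix>[NLSCAQ]?)$"
)


class AlleleNameError(ValueError):
    """Raised for names that do not parse as two-field-or-better HLA alleles."""


@dataclass(frozen=True, order=True)
class AlleleName:
    """A parsed HLA allele name at two-field or higher resolution.

    Field strings keep their original zero-padding so that
    ``format(parse(s)) == s`` for every valid input.
    """

    locus: str
    fields: tuple[str, ...]
    suffix: str = ""

    def __post_init__(self) -> None:
        if self.locus not in SUPPORTED_LOCI:
            raise AlleleNameError(f"unsupported locus {self.locus!r}")
        if len(self.fields) < 2:
            raise AlleleNameError(
                f"{self.locus}*{':'.join(self.fields)}: at least two fields required"
            )

    @property
    def is_null(self) -> bool:
        return self.suffix == "N"

    def two_field(self) -> "AlleleName":
        """Truncate to two fields (protein-level resolution); suffix kept."""
        if len(self.fields) == 2:
            return self
        return AlleleName(self.locus, self.fields[:2], self.suffix)

    def __str__(self) -> str:
        return f"{self.locus}*{':'.join(self.fields)}{self.suffix}"


def parse_allele(name: str) -> AlleleName:
    """Parse ``'DQB1*06:02'`` into an :class:`AlleleName`.

    Raises :class:`AlleleNameError` on malformed names, unsupported loci or
    fewer than two fields.
    """
    m = _ALLELE_RE.match(name.strip())
    if m is None:
        raise AlleleNameError(f"malformed allele name {name!r}")
    return AlleleName(m.group("locus"), tuple(m.group("fields").split(":")),
                      m.group("suffix"))


def format_allele(allele: AlleleName) -> str:
    return str(allele)
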