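"""Protein variant identifiers and isoform coordinate mapping.

Variants are represented at the amino-acid level in HGVS-p short form
(``p.R167Q``), with ``*`` for stop gains and ``=`` for synonymous changes.
Two isoforms of the same protein are supported, differing by an N-terminal
truncation: the "ubiquitous" isoform carries ``N_TERMINAL_OFFSET`` extra
residues ahead of the "erythroid" isoform, so erythroid position 1 is
ubiquitous position 18.  The ubiquitous frame is the canonical coordinate
system throughout the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"
SYNONYMOUS = "="

UBIQUITOUS = "ubiquitous"
ERYTHROID = "erythroid"

#: Residues present at the N-terminus of the ubiquitous isoform but absent
#: from the erythroid isoform.
N_TERMINAL_OFFSET = 17

_VARIANT_RE = re.compile(
    r"^(?:p\.)?"
    r"(?P<ref>[A-Z])"
    r"(?P<pos>\d+)"
    r"(?P<alt>[A-Z]|\*|=|Ter)$"
)


class VariantParseError(ValueError):
    """Raised when a variant string cannot be interpreted."""


@dataclass(frozen=True, order=True)
class ProteinVariant:
    """A single amino-acid substitution, nonsense or synonymous change.

    Attributes
    ----------
    position : int
        1-based residue index in the coordinate frame of `isoform`.
    ref_aa : str
        Single-letter wild-type residue.
    alt_aa : str
        Single-letter substituted residue, ``*`` for stop, ``=`` for
        synonymous.
    isoform : str
        Coordinate frame the position refers to.
    """

    position: int
    ref_aa: str
    alt_aa: str
    isoform: str = UBIQUITOUS

    def __post_init__(self) -> None:
        if self.position < 1:
            raise VariantParseError(f"position must be >= 1, got {self.position}")
        if self.ref_aa not in AMINO_ACIDS:
            raise VariantParseError(f"unknown reference residue {self.ref_aa!r}")
        if self.alt_aa not in AMINO_ACIDS and self.alt_aa not in (STOP, SYNONYMOUS):
            raise VariantParseError(f"unknown substituted residue {self.alt_aa!r}")
        if self.alt_aa == self.ref_aa:
            raise VariantParseError(
                f"{self.ref_aa}{self.position}{self.alt_aa}: identical reference "
                f"and substituted residue is not a variant (use '=' for synonymous)"
            )
        if self.isoform not in (UBIQUITOUS, ERYTHROID):
            raise VariantParseError(f"unknown isoform {self.isoform!r}")

    @property
    def var_class(self) -> str:
        """One of ``missense``, ``nonsense``, ``synonymous``."""
        if self.alt_aa == STOP:
            return "nonsense"
        if self.alt_aa == SYNONYMOUS:
            return "synonymous"
        return "missense"

    def __str__(self) -> str:
        return format_variant(self)


def parse_variant(text: str, isoform: str = UBIQUITOUS) -> ProteinVariant:
    """Parse an HGVS-p short-form or bare variant string.

    Accepts ``p.R167Q``, ``R167Q``, ``p.C261*``, ``p.C261Ter`` and the
    synonymous form ``p.A31=``.
    """
    m = _VARIANT_RE.match(text.strip())
    if m is None:
        raise VariantParseError(f"cannot parse variant string {text!r}")
    alt = m.group("alt")
    if alt == "Ter":
        alt = STOP
    return ProteinVariant(
        position=int(m.group("pos")),
        ref_aa=m.group("ref"),
        alt_aa=alt,
        isoform=isoform,
    )


def format_variant(variant: ProteinVariant, hgvs: bool = True) -> str:
    """Serialize a variant; inverse of :func:`parse_variant`."""
    prefix = "p." if hgvs else ""
    return f"{prefix}{variant.ref_aa}{variant.position}{variant.alt_aa}"


def map_isoform_coordinates(variant: ProteinVariant, to_isoform: str) -> ProteinVariant:
    """Re-express a variant in the other isoform's residue numbering.

    Ubiquitous position = erythroid position + 17.  Ubiquitous positions
    1..17 have no erythroid image.

    Raises
    ------
    ValueError
        If the target position does not exist in the destination isoform.
    """
    if to_isoform not in (UBIQUITOUS, ERYTHROID):
        raise VariantParseError(f"unknown isoform {to_isoform!r}")
    if variant.isoform == to_isoform:
        return variant
    if to_isoform == UBIQUITOUS:
        new_pos = variant.position + N_TERMINAL_OFFSET
    else:
        new_pos = variant.position - N_TERMINAL_OFFSET
        if new_pos < 1:
            raise ValueError(
                f"ubiquitous position {variant.position} lies in the N-terminal "
                f"extension and has no erythroid-isoform image"
            )
    return replace(variant, position=new_pos, isoform=to_isoform)
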