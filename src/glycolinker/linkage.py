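"""Glycosidic linkage nomenclature and cell-wall fraction labels.

A linkage code such as ``4-Glcp`` denotes a glucopyranose residue
glycosidically substituted at C-4; ``t-Araf`` is a terminal (non-reducing
end) arabinofuranose.  In carboxyl-reduced PMAA analysis the uronic acids
(GalA, GlcA) survive as 6,6-dideuterio neutral sugars but keep their uronic
names in the nomenclature; the deuterium label is carried only as a boolean
property, never as a spectral mass shift.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ValidationError

#: Monosaccharides recognised in linkage codes.
SUGARS = ("Ara", "Xyl", "Glc", "Gal", "Man", "Rha", "Fuc", "GalA", "GlcA")

#: Sugars that derive from carboxyl-reduced uronic acids.
URONIC_SUGARS = frozenset({"GalA", "GlcA"})

_ALLOWED_POSITIONS = frozenset({2, 3, 4, 5, 6})

# Longest sugar names first so "GalA" is not read as "Gal" + trailing "A".
_SUGAR_ALTERNATION = "|".join(sorted(SUGARS, key=len, reverse=True))
_LINKAGE_RE = re.compile(
    rf"^(?P<pos>t|\d(?:,\d)*)-(?P<sugar>{_SUGAR_ALTERNATION})(?P<ring>[pf])$"
)


@dataclass(frozen=True)
class LinkageCode:
    """A glycosidic linkage type, e.g. ``2,4-Rhap`` or ``t-Galp``.

    Equality, ordering and hashing follow the canonical string form, so
    instances are safe dictionary keys.
    """

    sugar: str
    ring_form: str
    linked_positions: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.sugar not in SUGARS:
            raise ValidationError(f"unknown sugar {self.sugar!r}")
        if self.ring_form not in ("p", "f"):
            raise ValidationError(f"ring form must be 'p' or 'f', got {self.ring_form!r}")
        positions = frozenset(self.linked_positions)
        if not positions <= _ALLOWED_POSITIONS:
            bad = sorted(positions - _ALLOWED_POSITIONS)
            raise ValidationError(f"linked positions {bad} outside carbons 2-6")
        object.__setattr__(self, "linked_positions", positions)

    @property
    def is_terminal(self) -> bool:
        return not self.linked_positions

    @property
    def uronic_origin(self) -> bool:
        """True for residues derived from carboxyl-reduced uronic acids."""
        return self.sugar in URONIC_SUGARS

    @classmethod
    def parse(cls, text: str) -> "LinkageCode":
        m = _LINKAGE_RE.match(text.strip())
        if m is None:
            raise ValidationError(f"cannot parse linkage code {text!r}")
        pos = m.group("pos")
        positions = frozenset() if pos == "t" else frozenset(int(p) for p in pos.split(","))
        return cls(m.group("sugar"), m.group("ring"), positions)

    def __str__(self) -> str:
        prefix = "t" if self.is_terminal else ",".join(str(p) for p in sorted(self.linked_positions))
        return f"{prefix}-{self.sugar}{self.ring_form}"

    def __repr__(self) -> str:  # compact; the canonical form is unambiguous
        return f"LinkageCode({str(self)!r})"

    # Ordering by canonical string keeps tie-breaks deterministic everywhere.
    def __lt__(self, other: "LinkageCode") -> bool:
        return str(self) < str(other)

    def __le__(self, other: "LinkageCode") -> bool:
        return str(self) <= str(other)


#: Allowed fraction names per extraction scheme.
FRACTION_SCHEMES: dict[str, tuple[str, ...]] = {
    # ELISA sequential extraction series of the whole cell wall
    "ELISA-series": ("AO", "SC", "1M KOH", "4M KOH", "CH", "4M KOHPC"),
    # MAPP microarray extraction series
    "MAPP-series": ("CDTA", "NaOH", "cellulase"),
    # Linkage-analysis fractionation series (EDTA and Na2CO3 extracts pooled)
    "linkage-series": ("EDTA+Na2CO3", "4M KOH", "Residue"),
    # Unfractionated de-starched cell wall
    "whole": ("AIR", "whole-wall"),
}


@dataclass(frozen=True)
class FractionLabel:
    """A named cell-wall fraction within an extraction scheme."""

    scheme: str
    name: str
    pretreatment: str | None = None  # e.g. "NaBD4"

    def __post_init__(self) -> None:
        if self.scheme not in FRACTION_SCHEMES:
            raise ValidationError(
                f"unknown scheme {self.scheme!r}; expected one of {sorted(FRACTION_SCHEMES)}"
            )
        allowed = FRACTION_SCHEMES[self.scheme]
        if self.name not in allowed:
            raise ValidationError(
                f"fraction {self.name!r} not in scheme {self.scheme!r} (allowed: {allowed})"
            )

    def __str__(self) -> str:
        tag = f"+{self.pretreatment}" if self.pretreatment else ""
        return f"{self.name}{tag}"


def whole_wall(pretreatment: str | None = None) -> FractionLabel:
    """Convenience constructor for the unfractionated cell wall."""
    return FractionLabel("whole", "AIR", pretreatment)
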