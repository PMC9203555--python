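"""Protein variant panel: names, melting temperatures, wild-type flag.

The default panel mimics a set of point mutants of a small two-state
folder spanning melting temperatures from well below to slightly above
the growth temperature, with exactly one wild-type reference at
Tm = 55 degC.  The non-wild-type Tm values are synthetic fixture values
chosen to cover that range; only their ordering and span matter to the
analyses downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ValidationError

__all__ = ["VariantSpec", "default_panel", "tm_map", "validate_panel"]


@dataclass(frozen=True)
class VariantSpec:
    """A named protein variant with its in-vitro melting temperature."""

    name: str
    tm_celsius: float
    description: str = ""
    is_wild_type: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("variant name must be non-empty")
        if not math.isfinite(self.tm_celsius):
            raise ValidationError(f"variant {self.name!r}: tm_celsius must be finite")


def default_panel() -> list[VariantSpec]:
    """Eight-variant fixture panel, ordered by melting temperature.

    Exactly one variant is flagged wild type (Tm = 55 degC).  Two
    variants share Tm = 55 degC on purpose: a surface mutation that
    retains stability is indistinguishable from wild type on the
    stability axis, which exercises tie handling in the rank statistics.
    """
    return [
        VariantSpec("L57G", 8.0, "core mutation, strongly destabilised"),
        VariantSpec("L57C", 25.0, "core mutation, destabilised"),
        VariantSpec("L57P", 35.0, "core mutation, destabilised"),
        VariantSpec("M40A", 45.0, "core mutation, mildly destabilised"),
        VariantSpec("wt", 55.0, "wild-type reference", is_wild_type=True),
        VariantSpec("Q33S", 55.0, "surface mutation, stability retained"),
        VariantSpec("Q33Y", 58.0, "surface mutation, stabilised"),
        VariantSpec("V36I", 61.0, "core mutation, stabilised"),
    ]


def tm_map(panel: list[VariantSpec]) -> dict[str, float]:
    """Name -> Tm lookup; rejects duplicate names."""
    names = [v.name for v in panel]
    if len(set(names)) != len(names):
        raise ValidationError("variant panel contains duplicate names")
    return {v.name: v.tm_celsius for v in panel}


def validate_panel(panel: list[VariantSpec]) -> None:
    """Full-panel invariants: distinct names, exactly one wild type."""
    tm_map(panel)
    n_wt = sum(v.is_wild_type for v in panel)
    if n_wt != 1:
        raise ValidationError(f"variant panel must flag exactly one wild type (got {n_wt})")
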