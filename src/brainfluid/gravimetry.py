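"""Gravimetric brain water content.

After desiccation of a hemisphere, brain water is reported in two
normalizations that are both in common use in the oedema literature:

* percent water content, ``100 * (wet - dry) / wet`` — intuitive but
  compresses real oedema changes into fractions of a percentage point;
* water per dry matter, ``(wet - dry) / dry`` in g water / g dry weight —
  a small percent-point change maps onto a several-percent change here,
  which is why both are reported.

The two are algebraically equivalent; :func:`wet_to_dry_normalization` and
:func:`dry_to_wet_normalization` convert between them.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "GravimetryRecord",
    "percent_water_content",
    "water_per_dry",
    "wet_to_dry_normalization",
    "dry_to_wet_normalization",
]


@dataclass(frozen=True)
class GravimetryRecord:
    """Wet/dry hemisphere weights for one animal.

    Invariant: ``wet_g >= dry_g > 0`` (desiccation removes mass, never adds).
    """

    animal_id: str
    strain: str
    wet_g: float
    dry_g: float

    def __post_init__(self) -> None:
        _check_weights(self.wet_g, self.dry_g)

    @property
    def percent_water(self) -> float:
        return percent_water_content(self.wet_g, self.dry_g)

    @property
    def water_per_dry(self) -> float:
        return water_per_dry(self.wet_g, self.dry_g)


def _check_weights(wet_g: float, dry_g: float) -> None:
    if dry_g <= 0 or wet_g <= 0:
        raise ValueError(f"weights must be positive, got wet={wet_g}, dry={dry_g}")
    if wet_g < dry_g:
        raise ValueError(f"wet weight {wet_g} g below dry weight {dry_g} g")


def percent_water_content(wet_g: float, dry_g: float) -> float:
    """Water content as percent of wet weight: ``100 * (wet - dry) / wet``."""
    _check_weights(wet_g, dry_g)
    return 100.0 * (wet_g - dry_g) / wet_g


def water_per_dry(wet_g: float, dry_g: float) -> float:
    """Water per unit dry matter: ``(wet - dry) / dry`` in g/g."""
    _check_weights(wet_g, dry_g)
    return (wet_g - dry_g) / dry_g


def wet_to_dry_normalization(percent: float) -> float:
    """Convert percent water content to g water / g dry weight.

    ``f = percent/100`` is the water mass fraction of the wet tissue, so the
    dry-normalized content is ``f / (1 - f)``.
    """
    if not 0.0 <= percent < 100.0:
        raise ValueError(f"percent water content must lie in [0, 100), got {percent}")
    f = percent / 100.0
    return f / (1.0 - f)


def dry_to_wet_normalization(g_per_g: float) -> float:
    """Inverse of :func:`wet_to_dry_normalization`: g/g dry back to percent."""
    if g_per_g < 0:
        raise ValueError(f"water per dry weight must be non-negative, got {g_per_g}")
    return 100.0 * g_per_g / (1.0 + g_per_g)
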