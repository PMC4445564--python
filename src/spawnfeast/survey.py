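"""Standing-stock estimation from stratified beach surveys.

Converts quadrat egg surveys (percent cover and layer counts) and sediment-core
amphipod samples into dry-mass standing stocks, expressed per 1-m-wide strip of
beach running perpendicular to the shoreline from the supratidal down to the
low intertidal.

The egg conversion divides covered area by the projected footprint of a single
egg (``pi * r**2``) and multiplies by the mean number of egg layers; attached
eggs are additionally multiplied by the mean number of egg-bearing macrophyte
layers.  No packing-fraction correction is applied by default — percent cover
is read as projected area — but :class:`EggGeometry.packing_fraction` exposes
one for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "STRATA",
    "CORE_STRATA",
    "EggGeometry",
    "QuadratObservation",
    "StratumLayout",
    "SedimentCore",
    "StandingStock",
    "loose_egg_count",
    "attached_egg_count",
    "quadrat_egg_mass",
    "strip_egg_mass",
    "amphipod_core_density",
    "strip_amphipod_mass",
]

#: Tidal strata sampled by quadrats, low intertidal to old supratidal wrack.
STRATA = ("low_1_2m", "mid_2_3m", "high_3_4m", "fresh_wrack", "old_wrack")

#: Upper strata where amphipods occur and sediment cores are taken.
CORE_STRATA = ("high_3_4m", "fresh_wrack", "old_wrack")

MG_PER_KG = 1e6


@dataclass(frozen=True)
class EggGeometry:
    """Geometry and mass constants for a single herring egg.

    Parameters
    ----------
    egg_radius_mm : float
        Egg radius in millimetres (default 0.74, a conservative literature
        value for Pacific herring).
    per_egg_dry_mass_mg : float
        Dry mass of one egg in milligrams (default 0.27).
    packing_fraction : float
        Optional multiplier on eggs-per-covered-area, default 1.0 (cover is
        read as projected area with no packing correction).
    """

    egg_radius_mm: float = 0.74
    per_egg_dry_mass_mg: float = 0.27
    packing_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.egg_radius_mm <= 0 or self.per_egg_dry_mass_mg <= 0:
            raise ValueError("egg radius and per-egg mass must be positive")
        if self.packing_fraction <= 0:
            raise ValueError("packing_fraction must be positive")

    @property
    def footprint_m2(self) -> float:
        """Projected area of one egg in square metres."""
        r_m = self.egg_radius_mm * 1e-3
        return math.pi * r_m**2


def _check_cover(name: str, value: float) -> None:
    if not 0.0 <= value <= 100.0:
        raise ValueError(f"{name} must be in [0, 100], got {value}")


@dataclass(frozen=True)
class QuadratObservation:
    """One 0.25-m2 egg-survey quadrat at a tidal stratum.

    ``loose`` eggs lie free on the substrate; ``attached`` eggs adhere to
    macrophytes, so their count also scales with the number of egg-bearing
    macrophyte layers.  Layer counts are the up-to-five random depth counts
    taken within the quadrat; an empty count list is valid only when the
    corresponding cover is zero.
    """

    beach_id: str
    survey_date: str
    stratum: str
    quadrat_area_m2: float = 0.25
    loose_cover_pct: float = 0.0
    loose_layer_counts: Sequence[float] = ()
    attached_cover_pct: float = 0.0
    attached_egg_layer_counts: Sequence[float] = ()
    macrophyte_layer_counts: Sequence[float] = ()

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise ValueError(f"unknown stratum {self.stratum!r}; expected one of {STRATA}")
        if self.quadrat_area_m2 <= 0:
            raise ValueError("quadrat_area_m2 must be positive")
        _check_cover("loose_cover_pct", self.loose_cover_pct)
        _check_cover("attached_cover_pct", self.attached_cover_pct)
        for label, counts in (
            ("loose_layer_counts", self.loose_layer_counts),
            ("attached_egg_layer_counts", self.attached_egg_layer_counts),
            ("macrophyte_layer_counts", self.macrophyte_layer_counts),
        ):
            if any(c < 0 for c in counts):
                raise ValueError(f"{label} must be non-negative")

    def _ident(self) -> str:
        return f"quadrat(beach={self.beach_id}, date={self.survey_date}, stratum={self.stratum})"


@dataclass(frozen=True)
class StratumLayout:
    """Horizontal width (m) of each tidal stratum along the 1-m strip.

    Widths are field geometry measured per beach; strata without eggs may be
    omitted and are treated as width 0 only when no quadrats reference them.
    """

    beach_id: str
    widths: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for stratum, width in self.widths.items():
            if stratum not in STRATA:
                raise ValueError(f"unknown stratum {stratum!r} in layout for {self.beach_id}")
            if width < 0:
                raise ValueError(f"negative width for stratum {stratum!r}")


@dataclass(frozen=True)
class SedimentCore:
    """One amphipod sediment core (default diameter 10.6 cm, 10 cm deep).

    Samples are sieved and a fixed fraction (default 30%) sorted for
    amphipods; scaling to the whole core assumes homogeneous mixing before
    subsampling.
    """

    beach_id: str
    stratum: str
    sorted_dry_mass_g: float
    core_diameter_cm: float = 10.6
    sorted_fraction: float = 0.30

    def __post_init__(self) -> None:
        if self.stratum not in CORE_STRATA:
            raise ValueError(
                f"cores are taken in the upper strata {CORE_STRATA}, got {self.stratum!r}"
            )
        if not 0.0 < self.sorted_fraction <= 1.0:
            raise ValueError("sorted_fraction must be in (0, 1]")
        if self.sorted_dry_mass_g < 0:
            raise ValueError("sorted_dry_mass_g must be non-negative")
        if self.core_diameter_cm <= 0:
            raise ValueError("core_diameter_cm must be positive")

    @property
    def area_m2(self) -> float:
        r_m = self.core_diameter_cm / 2 * 1e-2
        return math.pi * r_m**2


@dataclass(frozen=True)
class StandingStock:
    """Egg and amphipod dry mass (kg) per 1-m-wide strip of one beach."""

    beach_id: str
    year: int
    egg_mass_kg: float
    amphipod_mass_kg: float

    def __post_init__(self) -> None:
        if self.egg_mass_kg < 0 or self.amphipod_mass_kg < 0:
            raise ValueError("standing-stock masses must be non-negative")


def _layer_mean(counts: Sequence[float], cover: float, obs: QuadratObservation, label: str) -> float:
    if cover == 0:
        return 0.0
    if not counts:
        raise ValueError(f"{obs._ident()}: positive {label} cover but no layer counts recorded")
    return sum(counts) / len(counts)


def loose_egg_count(obs: QuadratObservation, geom: EggGeometry = EggGeometry()) -> float:
    """Number of loose eggs in the quadrat.

    Covered area ``loose_cover/100 * quadrat_area`` divided by one egg
    footprint, times the mean layer count.
    """
    layers = _layer_mean(obs.loose_layer_counts, obs.loose_cover_pct, obs, "loose")
    if obs.loose_cover_pct == 0:
        return 0.0
    covered = obs.loose_cover_pct / 100.0 * obs.quadrat_area_m2
    return covered / geom.footprint_m2 * geom.packing_fraction * layers


def attached_egg_count(obs: QuadratObservation, geom: EggGeometry = EggGeometry()) -> float:
    """Number of attached eggs: cover-derived count x egg layers x macrophyte layers."""
    if obs.attached_cover_pct == 0:
        return 0.0
    egg_layers = _layer_mean(
        obs.attached_egg_layer_counts, obs.attached_cover_pct, obs, "attached-egg"
    )
    macro_layers = _layer_mean(
        obs.macrophyte_layer_counts, obs.attached_cover_pct, obs, "macrophyte"
    )
    covered = obs.attached_cover_pct / 100.0 * obs.quadrat_area_m2
    return covered / geom.footprint_m2 * geom.packing_fraction * egg_layers * macro_layers


def quadrat_egg_mass(obs: QuadratObservation, geom: EggGeometry = EggGeometry()) -> float:
    """Total egg dry mass (kg) in the quadrat: (loose + attached) x per-egg mass."""
    n_eggs = loose_egg_count(obs, geom) + attached_egg_count(obs, geom)
    return n_eggs * geom.per_egg_dry_mass_mg / MG_PER_KG


def strip_egg_mass(
    quadrats: Iterable[QuadratObservation],
    layout: StratumLayout,
    geom: EggGeometry = EggGeometry(),
) -> float:
    """Egg dry mass (kg) for a 1-m-wide beach strip.

    Per stratum: mean per-m2 egg mass across that stratum's quadrats times the
    stratum's horizontal width (x 1 m of shoreline), summed over strata.
    A stratum sampled by quadrats must have a width in the layout; strata
    absent from both contribute zero.
    """
    by_stratum: dict[str, list[float]] = {}
    for obs in quadrats:
        density = quadrat_egg_mass(obs, geom) / obs.quadrat_area_m2  # kg / m2
        by_stratum.setdefault(obs.stratum, []).append(density)

    total = 0.0
    for stratum, densities in by_stratum.items():
        if stratum not in layout.widths:
            raise ValueError(
                f"stratum {stratum!r} has quadrats but no width in layout for "
                f"beach {layout.beach_id}"
            )
        total += sum(densities) / len(densities) * layout.widths[stratum]
    return total


def amphipod_core_density(core: SedimentCore) -> float:
    """Amphipod dry-mass density (g per m2) implied by one sediment core.

    The sorted mass is scaled up by the sorted fraction, then divided by the
    core's cross-sectional area.
    """
    whole_core_g = core.sorted_dry_mass_g / core.sorted_fraction
    return whole_core_g / core.area_m2


def strip_amphipod_mass(cores: Iterable[SedimentCore], layout: StratumLayout) -> float:
    """Amphipod dry mass (kg) per 1-m strip, summed over the upper strata.

    Amphipod mass per beach is treated as constant over the season (the
    sampled population is overwintered adults; juveniles pass the sieve).
    """
    by_stratum: dict[str, list[float]] = {}
    for core in cores:
        by_stratum.setdefault(core.stratum, []).append(amphipod_core_density(core))

    total_g = 0.0
    for stratum, densities in by_stratum.items():
        if stratum not in layout.widths:
            raise ValueError(
                f"stratum {stratum!r} has cores but no width in layout for "
                f"beach {layout.beach_id}"
            )
        total_g += sum(densities) / len(densities) * layout.widths[stratum]
    return total_g / 1000.0
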