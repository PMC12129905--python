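"""Species presets and injury time-courses for the synthetic whole-mount generator.

Each :class:`SpeciesPreset` bundles the biology one species/age contributes to a
simulation: retinal area, target RGC density, the ventrotemporal density
gradient of teleost retinas, soma size, the optic-nerve-crush survival
time-course, and (for young killifish) ongoing retinal growth.

Built-in presets encode the published young-adult mouse (10 weeks), adult
zebrafish (21 weeks) and young/old African turquoise killifish (6/18 weeks)
values: mean whole-retina densities of 3,179, 17,390, 17,769 and 14,041
RGCs/mm^2 and total counts of 44,499, 66,262, 74,597 and 132,159 RGCs
respectively, with retinal areas derived as count / density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

__all__ = [
    "InjuryCourse",
    "SpeciesPreset",
    "make_preset",
    "survival_fraction",
    "builtin_preset_keys",
    "PresetError",
]

SPECIES = ("mouse", "zebrafish", "killifish")
QUADRANTS = ("DN", "DT", "VN", "VT")


class PresetError(ValueError):
    """Unknown species/age combination or invalid preset parameters."""


@dataclass(frozen=True)
class InjuryCourse:
    """Piecewise-linear RGC survival fraction vs. days post optic nerve crush.

    ``anchors`` is an ordered sequence of ``(dpi, surviving_fraction)`` pairs;
    the first anchor must be ``(0, 1.0)`` (uninjured baseline), dpi strictly
    increasing, fractions within [0, 1]. Between anchors the fraction is
    linearly interpolated; beyond the last anchor it is held constant.
    """

    anchors: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.anchors:
            raise PresetError("injury course needs at least one anchor")
        a = tuple((float(d), float(f)) for d, f in self.anchors)
        object.__setattr__(self, "anchors", a)
        if a[0] != (0.0, 1.0):
            raise PresetError("first injury anchor must be (0, 1.0)")
        days = [d for d, _ in a]
        if any(d2 <= d1 for d1, d2 in zip(days, days[1:])):
            raise PresetError("injury anchor dpi must be strictly increasing")
        if any(not (0.0 <= f <= 1.0) for _, f in a):
            raise PresetError("survival fractions must lie in [0, 1]")

    def __call__(self, dpi: float) -> float:
        return survival_fraction(self, dpi)


def survival_fraction(course: InjuryCourse, dpi: float) -> float:
    """Surviving RGC fraction at ``dpi`` days post injury.

    Linear interpolation between the course's anchors; constant extrapolation
    beyond the last anchor. Negative ``dpi`` is a domain error.
    """
    dpi = float(dpi)
    if dpi < 0:
        raise ValueError(f"dpi must be >= 0, got {dpi}")
    days = np.array([d for d, _ in course.anchors])
    fracs = np.array([f for _, f in course.anchors])
    return float(np.interp(dpi, days, fracs))


@dataclass(frozen=True)
class SpeciesPreset:
    """All generator parameters for one species/age condition.

    Parameters
    ----------
    retinal_area : mm^2 of the flattened whole-mount at the preset age.
    target_density : uninjured RGCs/mm^2.
    gradient_peak_quadrant : quadrant where density peaks ("none" = uniform).
    gradient_contrast : quadrant-mean density ratio peak/opposite, >= 1.
    soma_diameter_mean, soma_diameter_sd : RGC soma FWHM in um.
    injury_course : survival fraction vs. dpi after optic nerve crush.
    area_growth_per_day : fractional retinal area growth per day (fish grow
        lifelong; only the young-killifish preset is nonzero by default).
    """

    species_id: str
    age_label: str
    retinal_area: float
    target_density: float
    gradient_peak_quadrant: str
    gradient_contrast: float
    soma_diameter_mean: float
    soma_diameter_sd: float
    injury_course: InjuryCourse
    area_growth_per_day: float = 0.0

    def __post_init__(self) -> None:
        if self.species_id not in SPECIES:
            raise PresetError(f"unknown species {self.species_id!r}")
        if self.retinal_area <= 0 or self.target_density <= 0:
            raise PresetError("retinal_area and target_density must be > 0")
        if self.soma_diameter_mean <= 0:
            raise PresetError("soma_diameter_mean must be > 0")
        if self.gradient_contrast < 1.0:
            raise PresetError("gradient_contrast must be >= 1")
        if self.gradient_peak_quadrant not in QUADRANTS + ("none",):
            raise PresetError(
                f"gradient_peak_quadrant must be one of {QUADRANTS + ('none',)}"
            )
        if self.area_growth_per_day < 0:
            raise PresetError("area_growth_per_day must be >= 0")

    @property
    def expected_count(self) -> float:
        """Expected uninjured total RGC count (area x density)."""
        return self.retinal_area * self.target_density

    def grown_area(self, dpi: float) -> float:
        """Retinal area (mm^2) after ``dpi`` days of growth."""
        return self.retinal_area * (1.0 + self.area_growth_per_day * float(dpi))


# Survival anchors: fractions of RGCs remaining at each dpi after crush.
_MOUSE_COURSE = InjuryCourse(((0, 1.00), (7, 0.41), (14, 0.19)))
_ZEBRAFISH_COURSE = InjuryCourse(((0, 1.00), (7, 1.00), (14, 0.97), (21, 0.88)))
_KILLI_YOUNG_COURSE = InjuryCourse(
    ((0, 1.00), (4, 0.79), (7, 0.79), (14, 0.67), (21, 0.67))
)
_KILLI_OLD_COURSE = InjuryCourse(
    ((0, 1.00), (4, 0.83), (7, 0.83), (14, 0.56), (21, 0.56))
)

# Areas derived as published count / published density.
_BUILTINS = {
    ("mouse", "10w"): dict(
        retinal_area=44499 / 3179,  # 13.998 mm^2
        target_density=3179.0,
        gradient_peak_quadrant="none",
        gradient_contrast=1.0,
        soma_diameter_mean=12.0,
        soma_diameter_sd=1.5,
        injury_course=_MOUSE_COURSE,
        area_growth_per_day=0.0,
    ),
    ("zebrafish", "21w"): dict(
        retinal_area=66262 / 17390,  # 3.810 mm^2
        target_density=17390.0,
        gradient_peak_quadrant="VT",
        gradient_contrast=1.6,
        soma_diameter_mean=6.5,
        soma_diameter_sd=1.0,
        injury_course=_ZEBRAFISH_COURSE,
        area_growth_per_day=0.0,
    ),
    ("killifish", "6w"): dict(
        retinal_area=74597 / 17769,  # 4.198 mm^2
        target_density=17769.0,
        gradient_peak_quadrant="VT",
        gradient_contrast=1.6,
        soma_diameter_mean=6.5,
        soma_diameter_sd=1.0,
        injury_course=_KILLI_YOUNG_COURSE,
        area_growth_per_day=0.004,
    ),
    ("killifish", "18w"): dict(
        retinal_area=132159 / 14041,  # 9.413 mm^2
        target_density=14041.0,
        gradient_peak_quadrant="VT",
        gradient_contrast=1.6,
        soma_diameter_mean=6.5,
        soma_diameter_sd=1.0,
        injury_course=_KILLI_OLD_COURSE,
        area_growth_per_day=0.0,
    ),
}


def builtin_preset_keys() -> Sequence[Tuple[str, str]]:
    """The (species_id, age_label) pairs with built-in parameter sets."""
    return tuple(_BUILTINS)


def make_preset(species_id: str, age_label: str, **overrides) -> SpeciesPreset:
    """Build a :class:`SpeciesPreset` for a built-in species/age combination.

    Keyword overrides replace individual fields (e.g. ``retinal_area=1.0`` for
    a scaled-down simulation that keeps density, soma size and gradient).
    Unknown combinations raise :class:`PresetError`.
    """
    key = (species_id, age_label)
    if key not in _BUILTINS:
        raise PresetError(
            f"no built-in preset for {species_id!r} at age {age_label!r}; "
            f"known: {sorted(_BUILTINS)}"
        )
    params = dict(_BUILTINS[key])
    params.update(overrides)
    return SpeciesPreset(species_id=species_id, age_label=age_label, **params)
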