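"""Domain containers for hydrographic casts and profile-shape extraction.

A *cast* is one station visit: an ordered set of depth levels carrying
temperature, salinity, pH and (optionally) the incubation-bottle and pigment
raw measurements from which primary production and chlorophyll *a* are
derived.  Depths are metres, positive down, with 0 m the sea surface; levels
are stored sorted by increasing depth.

The shape operations here (surface value, depth of the profile maximum,
median/min–max envelopes over a collection of casts) are the descriptive
statistics used to compare fjord zones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

FJORDS = ("Hornsund", "Kongsfjord")
ZONES = ("Glacier", "Inner", "Outer")


class ProfileError(ValueError):
    """Raised for structurally invalid casts or profile queries."""


@dataclass(frozen=True)
class BottleSet:
    """Light/dark 14C bottle activities and incubation metadata at one depth.

    ``dpm_added`` is the activity of the inoculated NaH14CO3 tracer (the
    denominator of the production equation).  ``k1`` corrects for
    subsampling, ``k2`` converts per-exposure to per-hour production
    (1/exposure_hours when left at None), and ``k3`` converts
    mgC dm^-3 to mgC m^-3.
    """

    dpm_light: tuple[float, ...]
    dpm_dark: tuple[float, ...]
    dpm_added: float
    exposure_hours: float = 2.0
    k1_subsample: float = 1.0
    k2_time: float | None = None
    k3_dimension: float = 1.0e3

    def __post_init__(self) -> None:
        if not self.dpm_light or not self.dpm_dark:
            raise ProfileError("bottle set needs at least one light and one dark bottle")
        if self.dpm_added <= 0:
            raise ProfileError("dpm_added must be positive")
        if self.exposure_hours <= 0:
            raise ProfileError("exposure_hours must be positive")
        if any(a < 0 for a in self.dpm_light + self.dpm_dark):
            raise ProfileError("bottle activities must be non-negative")
        if self.k1_subsample <= 0 or self.k3_dimension <= 0:
            raise ProfileError("k factors must be positive")
        if self.k2_time is not None and self.k2_time <= 0:
            raise ProfileError("k2 must be positive when given")

    @property
    def k2(self) -> float:
        """Time factor: explicit value, else 1/exposure (2 h -> 0.5)."""
        return self.k2_time if self.k2_time is not None else 1.0 / self.exposure_hours


@dataclass(frozen=True)
class PigmentSample:
    """Spectrophotometric inputs for one chlorophyll-a determination."""

    A665: float
    A750: float
    extract_vol_ml: float = 10.0
    filtered_vol_l: float = 1.0
    cuvette_cm: float = 1.0
    solvent: str = "ethanol96"

    def __post_init__(self) -> None:
        if self.A665 < 0 or self.A750 < 0:
            raise ProfileError("absorbances must be non-negative")
        if min(self.extract_vol_ml, self.filtered_vol_l, self.cuvette_cm) <= 0:
            raise ProfileError("volumes and path length must be positive")


@dataclass(frozen=True)
class Level:
    """One sampled depth of a cast."""

    depth_m: float
    temperature_C: float
    salinity_psu: float
    pH: float | None = None
    bottles: BottleSet | None = None
    chl_inputs: PigmentSample | None = None

    def __post_init__(self) -> None:
        if self.depth_m < 0:
            raise ProfileError(f"depth {self.depth_m} m is negative")
        if not -2.0 <= self.temperature_C <= 15.0:
            raise ProfileError(
                f"temperature {self.temperature_C} degC outside plausible fjord range [-2, 15]"
            )
        if not 0.0 <= self.salinity_psu <= 36.0:
            raise ProfileError(f"salinity {self.salinity_psu} outside [0, 36]")
        if self.pH is not None and not 6.0 <= self.pH <= 9.0:
            raise ProfileError(f"pH {self.pH} outside [6, 9]")


@dataclass
class Cast:
    """One station visit: ordered depth levels plus station metadata."""

    cast_id: str
    fjord: str
    zone: str
    date_utc: str
    levels: list[Level]
    exposure_start_utc: float = 6.0
    exposure_end_utc: float = 18.0

    def __post_init__(self) -> None:
        if self.fjord not in FJORDS:
            raise ProfileError(f"unknown fjord {self.fjord!r}; expected one of {FJORDS}")
        if self.zone not in ZONES:
            raise ProfileError(f"unknown zone {self.zone!r}; expected one of {ZONES}")
        if not self.levels:
            raise ProfileError("cast has no levels")
        if self.exposure_end_utc <= self.exposure_start_utc:
            raise ProfileError("exposure window must have positive duration")
        depths = [lv.depth_m for lv in self.levels]
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ProfileError("levels must be strictly increasing in depth")

    @property
    def depths(self) -> np.ndarray:
        return np.array([lv.depth_m for lv in self.levels], dtype=float)


@dataclass
class ProductionProfile:
    """Derived volumetric production Pe(z) for one cast, with summaries.

    ``Pe0`` is the 0 m sample (or the shallowest sample, flagged),
    ``z_max_Pe`` the sampled depth of the profile maximum, and ``Pi`` the
    0–30 m depth integral in mgC m^-2 day^-1 (filled in by the integrator).
    """

    cast_id: str
    points: list[tuple[float, float]]
    Pe0: float | None = None
    Pe0_substituted: bool = False
    z_max_Pe: float | None = None
    Pi: float | None = None
    flags: list[str] = field(default_factory=list)

    def finalize(self) -> "ProductionProfile":
        self.Pe0, self.Pe0_substituted = surface_value(self.points)
        self.z_max_Pe = depth_of_maximum(self.points)
        return self


@dataclass
class Envelope:
    """Per-depth median/min/max of one variable across casts on a common grid."""

    grid: np.ndarray
    median: np.ndarray
    min: np.ndarray
    max: np.ndarray
    n_casts: np.ndarray  # casts contributing at each grid depth

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ProfileError("envelope grid must be strictly increasing")


# ---------------------------------------------------------------------------
# shape operations


def _as_series(profile: Sequence[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    if len(profile) == 0:
        raise ProfileError("no levels")
    z = np.array([p[0] for p in profile], dtype=float)
    v = np.array([p[1] for p in profile], dtype=float)
    if np.any(np.diff(z) <= 0):
        raise ProfileError("profile depths must be sorted strictly ascending")
    return z, v


def surface_value(profile: Sequence[tuple[float, float]]) -> tuple[float, bool]:
    """Value at 0 m, or the shallowest sample as a flagged substitute.

    Returns ``(value, substituted)``; ``substituted`` is True when no 0 m
    sample exists and the shallowest sample stood in for it.  Never
    interpolates: "surface" always means an actual sample.
    """
    z, v = _as_series(profile)
    return float(v[0]), bool(z[0] != 0.0)


def depth_of_maximum(profile: Sequence[tuple[float, float]]) -> float:
    """Sampled depth of the largest value; ties go to the shallowest depth.

    The shallow tie-break is deterministic and conservative for
    light-limited water columns.  NaN values are ignored; an all-NaN
    profile is an error.
    """
    z, v = _as_series(profile)
    ok = np.isfinite(v)
    if not ok.any():
        raise ProfileError("all profile values missing")
    z, v = z[ok], v[ok]
    return float(z[int(np.argmax(v))])  # argmax returns the first (shallowest) max


def envelope(
    profiles: Iterable[Sequence[tuple[float, float]]],
    grid: Sequence[float],
) -> Envelope:
    """Median/min/max envelope of several profiles on a common depth grid.

    Each profile is linearly interpolated in depth onto ``grid``; grid
    depths outside a profile's sampled span exclude that profile at those
    depths (no extrapolation), and the per-depth contributing count is
    reported.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ProfileError("grid must be a non-empty strictly increasing 1-D sequence")
    rows = []
    for prof in profiles:
        z, v = _as_series(prof)
        interp = np.interp(grid, z, v)
        interp[(grid < z[0]) | (grid > z[-1])] = np.nan
        rows.append(interp)
    if not rows:
        raise ProfileError("empty cast list")
    stack = np.vstack(rows)
    n = np.sum(np.isfinite(stack), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN grid depths -> NaN
        med = np.nanmedian(stack, axis=0)
        lo = np.nanmin(stack, axis=0)
        hi = np.nanmax(stack, axis=0)
    return Envelope(grid=grid, median=med, min=lo, max=hi, n_casts=n)
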