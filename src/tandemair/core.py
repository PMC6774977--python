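"""Shared domain types, unit conventions and track geometry.

Conventions used throughout the package:

* planar local coordinates in metres (an equirectangular projection
  around the survey centroid is assumed upstream; at the ~10^5 m extent
  of a typical survey block the projection error is negligible);
* timestamps are seconds from survey start;
* the declination angle is measured from the horizontal, so 90 deg means
  directly below the aircraft and small angles point at the horizon;
* effort lengths are kilometres, sighting geometry is metres.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Platform",
    "Category",
    "Subjective",
    "SurveyConstants",
    "EffortLeg",
    "Segment",
    "Sighting",
    "angle_to_distance",
    "distance_to_angle",
    "sighting_separation",
    "cut_segments",
    "pair_segments",
]


class Platform(str, Enum):
    """The two independent observation platforms sharing one aircraft."""

    SCANS = "SCANS"
    MEGAFAUNA = "MEGAFAUNA"

    @classmethod
    def other(cls, platform: "Platform") -> "Platform":
        return cls.MEGAFAUNA if platform == cls.SCANS else cls.SCANS


class Category(str, Enum):
    """Sighting categories used for covariates and post-stratification."""

    CETACEAN = "cetacean"
    OTHER_MARINE_FAUNA = "other_marine_fauna"
    ANTHROPOGENIC = "anthropogenic"
    SEABIRD_FLYING = "seabird_flying"
    SEABIRD_RESTING = "seabird_resting"
    SEABIRD_GROUP = "seabird_group"


SEABIRD_CATEGORIES = frozenset(
    {Category.SEABIRD_FLYING, Category.SEABIRD_RESTING, Category.SEABIRD_GROUP}
)


class Subjective(str, Enum):
    POOR = "poor"
    MODERATE = "moderate"
    GOOD = "good"
    EXCELLENT = "excellent"


GOOD_SUBJECTIVE = frozenset({Subjective.MODERATE, Subjective.GOOD, Subjective.EXCELLENT})


@dataclass(frozen=True)
class SurveyConstants:
    """Fixed survey-protocol constants.

    Defaults follow the aerial protocol: 90 knots at 600 ft, a 500 m
    omnidirectional duplicate buffer, a 15 deg angle window, an 85 deg
    under-the-plane threshold, a 30 s covariate look-back and
    strip-transect widths of 200 m (seabirds) and 500 m (boats).
    """

    altitude: float = 183.0  # m
    speed_kmh: float = 167.0  # km/h
    buffer_radius: float = 500.0  # m
    angle_window: float = 15.0  # degrees
    under_plane_angle: float = 85.0  # degrees
    lookback: float = 30.0  # s
    seabird_strip: float = 200.0  # m
    boat_strip: float = 500.0  # m

    def __post_init__(self) -> None:
        for name in (
            "altitude",
            "speed_kmh",
            "buffer_radius",
            "angle_window",
            "lookback",
            "seabird_strip",
            "boat_strip",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 < self.angle_window < 90):
            raise ValueError("angle_window must lie in (0, 90)")
        if not (0 < self.under_plane_angle < 90):
            raise ValueError("under_plane_angle must lie in (0, 90)")

    @property
    def speed_ms(self) -> float:
        return self.speed_kmh / 3.6


@dataclass
class EffortLeg:
    """An on-effort track piece with homogeneous observation conditions."""

    leg_id: str
    transect_id: str
    platform: Platform
    t_start: float
    t_end: float
    x_start: float
    y_start: float
    x_end: float
    y_end: float
    length_km: float
    sea_state: int
    subjective: Subjective

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError(f"leg {self.leg_id}: t_end must exceed t_start")
        if self.length_km <= 0:
            raise ValueError(f"leg {self.leg_id}: length must be positive")
        if not 0 <= self.sea_state <= 6:
            raise ValueError(f"leg {self.leg_id}: sea_state outside Beaufort 0-6")
        chord = math.hypot(self.x_end - self.x_start, self.y_end - self.y_start) / 1000.0
        if chord > 0 and abs(chord - self.length_km) > 0.01 * max(chord, self.length_km):
            raise ValueError(
                f"leg {self.leg_id}: length {self.length_km:.3f} km inconsistent "
                f"with endpoint distance {chord:.3f} km"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class Segment:
    """A fixed-length subdivision of an effort leg (target 10 km)."""

    segment_id: str
    leg_id: str
    transect_id: str
    platform: Platform
    length_km: float
    t_start: float
    t_end: float
    x_start: float = 0.0
    y_start: float = 0.0
    x_end: float = 0.0
    y_end: float = 0.0
    is_remainder: bool = False
    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length_km <= 0:
            raise ValueError(f"segment {self.segment_id}: length must be positive")


@dataclass
class Sighting:
    """A single detection event recorded by one platform."""

    sighting_id: str
    platform: Platform
    time: float
    x: float
    y: float
    side: str  # "L" or "R"
    angle: float  # declination degrees, 90 = under the aircraft
    category: Category
    species: str
    group_size: int

    def __post_init__(self) -> None:
        if not 0 < self.angle <= 90:
            raise ValueError(
                f"sighting {self.sighting_id}: angle {self.angle} outside (0, 90]"
            )
        if self.side not in ("L", "R"):
            raise ValueError(f"sighting {self.sighting_id}: side must be 'L' or 'R'")
        if self.group_size < 1:
            raise ValueError(f"sighting {self.sighting_id}: group_size must be >= 1")
        if self.category == Category.SEABIRD_GROUP and self.group_size <= 10:
            raise ValueError(
                f"sighting {self.sighting_id}: seabird_group requires > 10 individuals"
            )

    def perp_distance(self, altitude: float = 183.0) -> float:
        return angle_to_distance(self.angle, altitude)


def angle_to_distance(angle: float, altitude: float) -> float:
    """Convert a declination angle to perpendicular distance (m).

    ``distance = altitude * tan(90 deg - angle)``; 90 deg is directly
    below the aircraft (distance 0) and the distance grows without bound
    as the angle approaches the horizon.
    """
    angle = np.asarray(angle, dtype=float) if np.ndim(angle) else float(angle)
    if np.any(np.asarray(angle) <= 0) or np.any(np.asarray(angle) > 90):
        raise ValueError(f"angle must lie in (0, 90], got {angle}")
    if altitude <= 0:
        raise ValueError("altitude must be positive")
    return altitude * np.tan(np.deg2rad(90.0 - angle))


def distance_to_angle(distance: float, altitude: float) -> float:
    """Inverse of :func:`angle_to_distance`; returns degrees in (0, 90]."""
    distance = np.asarray(distance, dtype=float) if np.ndim(distance) else float(distance)
    if np.any(np.asarray(distance) < 0):
        raise ValueError("distance must be non-negative")
    if altitude <= 0:
        raise ValueError("altitude must be positive")
    return 90.0 - np.rad2deg(np.arctan(distance / altitude))


def sighting_separation(s1: Sighting, s2: Sighting) -> float:
    """Euclidean distance (m) between the recorded points of two sightings."""
    for s in (s1, s2):
        if s.x is None or s.y is None or not (np.isfinite(s.x) and np.isfinite(s.y)):
            raise ValueError(f"sighting {s.sighting_id} lacks finite coordinates")
    return math.hypot(s1.x - s2.x, s1.y - s2.y)


_LEN_TOL = 1e-9


def cut_segments(legs: list[EffortLeg], target_len: float = 10.0) -> list[Segment]:
    """Subdivide effort legs into consecutive segments of ``target_len`` km.

    Each leg yields floor(length/target) full segments plus one shorter
    remainder (kept and flagged ``is_remainder``; dropping it would bias
    encounter rates). Times and endpoints are linearly interpolated along
    the leg. Total segment length equals total leg length to float
    tolerance.
    """
    if target_len <= 0:
        raise ValueError("target_len must be positive")
    segments: list[Segment] = []
    for leg in legs:
        n_full = int(math.floor(leg.length_km / target_len + _LEN_TOL))
        remainder = leg.length_km - n_full * target_len
        if remainder < _LEN_TOL * max(1.0, leg.length_km):
            remainder = 0.0
        pieces = [target_len] * n_full + ([remainder] if remainder > 0 else [])
        if not pieces:  # leg shorter than tolerance guard
            pieces = [leg.length_km]
        start = 0.0
        for i, piece in enumerate(pieces):
            f0 = start / leg.length_km
            f1 = min((start + piece) / leg.length_km, 1.0)
            segments.append(
                Segment(
                    segment_id=f"{leg.leg_id}-s{i}",
                    leg_id=leg.leg_id,
                    transect_id=leg.transect_id,
                    platform=leg.platform,
                    length_km=piece,
                    t_start=leg.t_start + f0 * leg.duration,
                    t_end=leg.t_start + f1 * leg.duration,
                    x_start=leg.x_start + f0 * (leg.x_end - leg.x_start),
                    y_start=leg.y_start + f0 * (leg.y_end - leg.y_start),
                    x_end=leg.x_start + f1 * (leg.x_end - leg.x_start),
                    y_end=leg.y_start + f1 * (leg.y_end - leg.y_start),
                    is_remainder=(i == n_full and remainder > 0),
                )
            )
            start += piece
    return segments


def _overlap(a: Segment, b: Segment) -> float:
    return max(0.0, min(a.t_end, b.t_end) - max(a.t_start, b.t_start))


def pair_segments(
    seg_a: list[Segment], seg_b: list[Segment]
) -> tuple[list[tuple[Segment, Segment]], list[Segment], list[Segment]]:
    """Pair segments of two platforms by maximal temporal overlap.

    Candidate pairs with positive overlap are matched one-to-one,
    largest overlap first (ties broken by earlier A start time, then
    segment ids, for determinism). Returns (pairs, unpaired_a,
    unpaired_b); a warning is raised if nothing overlaps at all.
    """
    seg_a = sorted(seg_a, key=lambda s: (s.t_start, s.segment_id))
    seg_b = sorted(seg_b, key=lambda s: (s.t_start, s.segment_id))
    candidates = []
    j0 = 0
    for ia, a in enumerate(seg_a):
        while j0 < len(seg_b) and seg_b[j0].t_end <= a.t_start:
            j0 += 1
        j = j0
        while j < len(seg_b) and seg_b[j].t_start < a.t_end:
            ov = _overlap(a, seg_b[j])
            if ov > 0:
                candidates.append((ov, ia, j))
            j += 1
    candidates.sort(
        key=lambda c: (-c[0], seg_a[c[1]].t_start, seg_a[c[1]].segment_id, seg_b[c[2]].segment_id)
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[Segment, Segment]] = []
    for ov, ia, ib in candidates:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        pairs.append((seg_a[ia], seg_b[ib]))
    unpaired_a = [s for i, s in enumerate(seg_a) if i not in used_a]
    unpaired_b = [s for i, s in enumerate(seg_b) if i not in used_b]
    if seg_a and seg_b and not pairs:
        warnings.warn("segment time ranges are disjoint: no pairs found", stacklevel=2)
    pairs.sort(key=lambda p: p[0].t_start)
    return pairs, unpaired_a, unpaired_b
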