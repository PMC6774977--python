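"""Descriptive platform comparison and encounter-rate post-stratification.

Encounter rates are sightings per km of effort, per platform and target
category. For the paired-segment comparison the sign convention is
MEGAFAUNA minus SCANS (negative values mean a higher SCANS rate).

Post-stratification builds five classes per target type from the
rearward (MEGAFAUNA) platform's segment encounter rates: class 1 holds
exactly-zero rates; classes 2-5 are the quartiles of the non-zero rates
(linear-interpolation percentiles; intervals closed on the left, open on
the right, the last class unbounded). Other marine fauna gets only two
classes (zero / non-zero). Classes propagate to the SCANS platform by
temporal segment matching, and per class x platform the conventional
distance sampling machinery estimates encounter rate, ESW and density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tandemair.core import Category, Platform, Segment, Sighting
from tandemair.cds import estimate_density, fit_detection

__all__ = [
    "ClassScheme",
    "StratifiedEstimate",
    "TARGET_CATEGORIES",
    "count_on_segments",
    "encounter_rates",
    "paired_difference",
    "make_classes",
    "stratified_cds",
]

# categories pooled per stratification target type
TARGET_CATEGORIES = {
    "anthropogenic": {Category.ANTHROPOGENIC},
    "seabird": {Category.SEABIRD_FLYING, Category.SEABIRD_RESTING, Category.SEABIRD_GROUP},
    "other_fauna": {Category.OTHER_MARINE_FAUNA},
}

# encounter-rate reporting categories (marine mammals = cetaceans here)
RATE_CATEGORIES = {
    "anthropogenic": {Category.ANTHROPOGENIC},
    "marine_mammals": {Category.CETACEAN},
    "other_marine_fauna": {Category.OTHER_MARINE_FAUNA},
    "seabirds": {Category.SEABIRD_FLYING, Category.SEABIRD_RESTING, Category.SEABIRD_GROUP},
}


@dataclass(frozen=True)
class ClassScheme:
    target_type: str
    thresholds: tuple  # ordered breakpoints of the non-zero rates
    n_classes: int

    def __post_init__(self) -> None:
        t = self.thresholds
        if any(t[i] >= t[i + 1] for i in range(len(t) - 1)):
            raise ValueError("thresholds must be strictly increasing")

    def assign(self, rate: float) -> int:
        """Class for one segment rate: 1 = exactly zero; then
        left-closed/right-open quartile intervals, last class unbounded."""
        if rate == 0.0:
            return 1
        for i, thr in enumerate(self.thresholds):
            if rate < thr:
                return i + 2
        return len(self.thresholds) + 2


@dataclass
class StratifiedEstimate:
    scheme: ClassScheme
    table: pd.DataFrame  # per class x platform
    flags: list = field(default_factory=list)


def merge_short_segments(segments: list[Segment], min_km: float = 5.0) -> list[Segment]:
    """Merge segments shorter than ``min_km`` into their predecessor on
    the same leg (rate stability for trailing remainders); heads shorter
    than the bound are kept as-is. Set ``min_km=0`` to disable."""
    if min_km <= 0:
        return list(segments)
    out: list[Segment] = []
    for seg in segments:
        if (out and seg.length_km < min_km and out[-1].leg_id == seg.leg_id):
            prev = out[-1]
            out[-1] = Segment(
                segment_id=prev.segment_id, leg_id=prev.leg_id,
                transect_id=prev.transect_id, platform=prev.platform,
                length_km=prev.length_km + seg.length_km,
                t_start=prev.t_start, t_end=seg.t_end,
                x_start=prev.x_start, y_start=prev.y_start,
                x_end=seg.x_end, y_end=seg.y_end,
                is_remainder=prev.is_remainder,
            )
        else:
            out.append(seg)
    return out


def count_on_segments(segments: list[Segment], sightings: list[Sighting],
                      categories: set[Category]) -> np.ndarray:
    """Number of qualifying sightings on each segment (by time interval)."""
    t0 = np.array([s.t_start for s in segments])
    t1 = np.array([s.t_end for s in segments])
    counts = np.zeros(len(segments), dtype=int)
    for s in sightings:
        if s.category not in categories:
            continue
        hits = np.flatnonzero((t0 <= s.time) & (s.time <= t1))
        if hits.size:
            counts[hits[0]] += 1
    return counts


def encounter_rates(sightings: dict, effort_km: dict,
                    categories: dict = RATE_CATEGORIES) -> pd.DataFrame:
    """Sightings per km of effort, per platform x category.

    Seabird rates are only reported for the MEGAFAUNA platform (the
    SCANS protocol does not record seabirds).
    """
    rows = []
    for platform, slist in sightings.items():
        eff = effort_km[platform]
        if eff <= 0:
            raise ValueError(f"zero effort for platform {platform}")
        for name, cats in categories.items():
            if name == "seabirds" and Platform(platform) == Platform.SCANS:
                continue
            n = sum(1 for s in slist if s.category in cats)
            rows.append({"platform": Platform(platform).value, "category": name,
                         "n": n, "effort_km": eff, "rate_per_km": n / eff})
    return pd.DataFrame(rows)


def paired_difference(pairs: list, sightings: dict,
                      categories: dict = RATE_CATEGORIES) -> pd.DataFrame:
    """Per-category mean and SD of per-segment rate differences.

    ``pairs`` come from :func:`tandemair.core.pair_segments` with the
    SCANS segments first. The difference is MEGAFAUNA - SCANS. The
    returned frame carries mean, SD, SE and whether the approximate 95%
    interval mean +/- 1.96 SE includes zero.
    """
    if not pairs:
        raise ValueError("no paired segments")
    seg_s = [p[0] for p in pairs]
    seg_m = [p[1] for p in pairs]
    rows = []
    for name, cats in categories.items():
        if name == "seabirds":
            continue  # not recordable on both platforms
        c_s = count_on_segments(seg_s, sightings[Platform.SCANS], cats)
        c_m = count_on_segments(seg_m, sightings[Platform.MEGAFAUNA], cats)
        r_s = c_s / np.array([s.length_km for s in seg_s])
        r_m = c_m / np.array([s.length_km for s in seg_m])
        diff = r_m - r_s
        mean = float(diff.mean())
        sd = float(diff.std(ddof=1)) if diff.size > 1 else np.nan
        se = sd / np.sqrt(diff.size) if diff.size > 1 else np.nan
        rows.append({
            "category": name, "n_pairs": diff.size, "mean_diff": mean,
            "sd_diff": sd, "se_diff": se,
            "zero_in_ci": bool(abs(mean) <= 1.96 * se) if np.isfinite(se) else None,
        })
    return pd.DataFrame(rows)


def make_classes(rates, target_type: str) -> ClassScheme:
    """Build the class scheme from MEGAFAUNA segment encounter rates."""
    rates = np.asarray(rates, dtype=float)
    if target_type not in TARGET_CATEGORIES:
        raise ValueError(f"unknown target type {target_type!r}")
    nonzero = rates[rates > 0]
    if nonzero.size == 0:
        warnings.warn(f"{target_type}: all rates zero, single class", stacklevel=2)
        return ClassScheme(target_type, (), 1)
    if target_type == "other_fauna":
        return ClassScheme(target_type, (), 2)  # zero / non-zero only
    if nonzero.size < 4:
        raise ValueError("need >= 4 non-zero rates for a five-class scheme")
    q25, q50, q75 = np.percentile(nonzero, [25, 50, 75])  # linear interpolation
    return ClassScheme(target_type, (float(q25), float(q50), float(q75)), 5)


def stratified_cds(
    segments: dict,
    pairs: list,
    sightings: dict,
    scheme: ClassScheme,
    cetacean_categories: set = frozenset({Category.CETACEAN}),
    truncation: float = 500.0,
    global_fits: dict | None = None,
    altitude: float = 183.0,
    min_class_sightings: int = 10,
) -> StratifiedEstimate:
    """Per-class, per-platform CDS estimates of pooled small cetaceans.

    Classes are assigned to MEGAFAUNA segments from their own target
    encounter rates and propagated to the paired SCANS segments. A class
    with fewer than ``min_class_sightings`` cetacean sightings inherits
    the platform's global detection fit (flagged). Density variance per
    class treats segments as the variance units.
    """
    flags: list[str] = []
    target_cats = TARGET_CATEGORIES[scheme.target_type]
    seg_m = segments[Platform.MEGAFAUNA]
    target_counts = count_on_segments(seg_m, sightings[Platform.MEGAFAUNA], target_cats)
    rates = target_counts / np.array([s.length_km for s in seg_m])
    class_of_m = {s.segment_id: scheme.assign(r) for s, r in zip(seg_m, rates)}

    class_of: dict = {Platform.MEGAFAUNA: class_of_m, Platform.SCANS: {}}
    for s_scans, s_mega in pairs:
        class_of[Platform.SCANS][s_scans.segment_id] = class_of_m[s_mega.segment_id]

    if global_fits is None:
        global_fits = {}
        for platform in (Platform.SCANS, Platform.MEGAFAUNA):
            d = [s.perp_distance(altitude) for s in sightings[platform]
                 if s.category in cetacean_categories]
            global_fits[platform] = fit_detection(d, "half_normal", truncation)

    rows = []
    for platform in (Platform.SCANS, Platform.MEGAFAUNA):
        segs = segments[platform]
        assigned = class_of[platform]
        cet = [s for s in sightings[platform] if s.category in cetacean_categories]
        for cls in range(1, scheme.n_classes + 1):
            cls_segs = [s for s in segs if assigned.get(s.segment_id) == cls]
            if not cls_segs:
                continue
            effort = sum(s.length_km for s in cls_segs)
            intervals = [(s.t_start, s.t_end) for s in cls_segs]
            cls_sight = [s for s in cet
                         if any(t0 <= s.time <= t1 for t0, t1 in intervals)]
            d = [s.perp_distance(altitude) for s in cls_sight]
            d = [x for x in d if x <= truncation]
            if len(d) >= min_class_sightings:
                fit = fit_detection(d, "half_normal", truncation)
            else:
                fit = global_fits[platform]
                flags.append(f"{platform.value}/class {cls}: "
                             f"{len(d)} sightings, global ESW inherited")
            pseudo_legs = _segments_as_legs(cls_segs)
            est = estimate_density(pseudo_legs, cls_sight, fit)
            rows.append({
                "target_type": scheme.target_type, "class": cls,
                "platform": platform.value, "effort_km": effort,
                "n_sightings": est.n_sightings,
                "encounter_rate": est.encounter_rate,
                "esw_m": fit.esw, "esw_cv": fit.esw_cv,
                "density": est.density, "cv": est.cv,
                "ci_low": est.ci_low, "ci_high": est.ci_high,
            })
    table = pd.DataFrame(rows)
    # CI-overlap indicator between platforms per class
    overlap = []
    for cls, grp in table.groupby("class"):
        if len(grp) == 2:
            a, b = grp.iloc[0], grp.iloc[1]
            overlap.append({"class": cls,
                            "ci_overlap": bool(a.ci_low <= b.ci_high and b.ci_low <= a.ci_high)})
    table.attrs["ci_overlap"] = pd.DataFrame(overlap)
    return StratifiedEstimate(scheme=scheme, table=table, flags=flags)


def _segments_as_legs(segments: list[Segment]):
    """View segments as effort legs so the density estimator can use
    them as variance units (each segment keeps its transect id)."""
    from tandemair.core import EffortLeg, Subjective

    legs = []
    for s in segments:
        legs.append(EffortLeg(
            leg_id=s.segment_id, transect_id=s.segment_id, platform=s.platform,
            t_start=s.t_start, t_end=s.t_end,
            x_start=s.x_start, y_start=s.y_start, x_end=s.x_end, y_end=s.y_end,
            length_km=s.length_km, sea_state=0, subjective=Subjective.GOOD,
        ))
    return legs
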