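"""Duplicate-sighting identification between the two platforms.

A deterministic decision tree classifies pairs of sightings as
duplicates: a platform-2 candidate is tested only inside an
omnidirectional buffer (default 500 m) around the platform-1 focal
sighting; it is rejected when the declination angles differ by more than
the angle window (default 15 deg); above the under-the-plane threshold
(default 85 deg) the observation side is ignored, otherwise the sides
must match; among several admissible candidates only the closest wins,
and matching is one-to-one.

Focal sightings are processed in time order and a consumed candidate
leaves the pool (greedy). Ties in separation are broken by earlier
recording time, then lower sighting id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tandemair.core import Sighting, sighting_separation

__all__ = [
    "DuplicateThresholds",
    "DuplicateResult",
    "find_duplicates",
    "brute_force_oracle",
    "sensitivity_sweep",
]


@dataclass(frozen=True)
class DuplicateThresholds:
    """Decision-tree thresholds (defaults 500 m / 15 deg / 85 deg)."""

    buffer_radius: float = 500.0
    angle_window: float = 15.0
    under_plane: float = 85.0

    def __post_init__(self) -> None:
        if self.buffer_radius <= 0:
            raise ValueError("buffer_radius must be positive")
        if not 0 <= self.angle_window < 90:
            raise ValueError("angle_window must lie in [0, 90)")
        if not 0 < self.under_plane < 90:
            raise ValueError("under_plane must lie in (0, 90)")


@dataclass
class DuplicateResult:
    matches: list[tuple[str, str, float]]  # (focal id, candidate id, separation m)
    unique_table: pd.DataFrame
    thresholds: DuplicateThresholds = field(default_factory=DuplicateThresholds)

    @property
    def n_matches(self) -> int:
        return len(self.matches)

    def match_pairs(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.matches}


def _admissible(focal: Sighting, cand: Sighting, thr: DuplicateThresholds,
                sep: float) -> bool:
    """The decision-tree predicate for one focal/candidate pair."""
    if sep > thr.buffer_radius:
        return False
    if abs(focal.angle - cand.angle) > thr.angle_window:
        return False
    if focal.angle > thr.under_plane or cand.angle > thr.under_plane:
        return True  # under the plane: visible from both sides
    return focal.side == cand.side


def _check_ids(sightings: list[Sighting]) -> None:
    ids = [s.sighting_id for s in sightings]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicated sighting ids in input")


def _build_unique_table(p1: list[Sighting], p2: list[Sighting],
                        matched: dict[str, str]) -> pd.DataFrame:
    """One row per unique sighting; duplicates represented by the focal
    (platform-1) record."""
    p2_by_id = {s.sighting_id: s for s in p2}
    rows = []
    for s in p1:
        partner = matched.get(s.sighting_id)
        rows.append(
            {
                "unique_id": s.sighting_id,
                "y_p1": 1,
                "y_p2": 1 if partner else 0,
                "time": s.time,
                "x": s.x,
                "y": s.y,
                "species_p1": s.species,
                "species_p2": p2_by_id[partner].species if partner else "",
                "id_p1": s.sighting_id,
                "id_p2": partner or "",
            }
        )
    consumed = set(matched.values())
    for s in p2:
        if s.sighting_id in consumed:
            continue
        rows.append(
            {
                "unique_id": s.sighting_id,
                "y_p1": 0,
                "y_p2": 1,
                "time": s.time,
                "x": s.x,
                "y": s.y,
                "species_p1": "",
                "species_p2": s.species,
                "id_p1": "",
                "id_p2": s.sighting_id,
            }
        )
    df = pd.DataFrame(rows, columns=["unique_id", "y_p1", "y_p2", "time", "x", "y",
                                     "species_p1", "species_p2", "id_p1", "id_p2"])
    return df.sort_values("time", kind="stable").reset_index(drop=True)


def find_duplicates(p1: list[Sighting], p2: list[Sighting],
                    thr: DuplicateThresholds | None = None) -> DuplicateResult:
    """Run the decision tree with platform 1 as the focal platform.

    Vectorized candidate search: separations and angle differences are
    computed with numpy; the greedy-in-time, closest-wins matching is
    then resolved sequentially.
    """
    thr = thr or DuplicateThresholds()
    _check_ids(p1 + p2)
    order = sorted(range(len(p1)), key=lambda i: (p1[i].time, p1[i].sighting_id))
    matched: dict[str, str] = {}
    if p2:
        x2 = np.array([s.x for s in p2])
        y2 = np.array([s.y for s in p2])
        a2 = np.array([s.angle for s in p2])
        t2 = np.array([s.time for s in p2])
        side2 = np.array([s.side for s in p2])
        id2 = np.array([s.sighting_id for s in p2])
        available = np.ones(len(p2), dtype=bool)
        for i in order:
            f = p1[i]
            sep = np.hypot(x2 - f.x, y2 - f.y)
            ok = available & (sep <= thr.buffer_radius)
            ok &= np.abs(a2 - f.angle) <= thr.angle_window
            if f.angle <= thr.under_plane:
                ok &= (a2 > thr.under_plane) | (side2 == f.side)
            if not ok.any():
                continue
            idx = np.flatnonzero(ok)
            # closest wins; ties by earlier time then lower id
            keys = sorted(idx, key=lambda j: (sep[j], t2[j], id2[j]))
            j = keys[0]
            matched[f.sighting_id] = str(id2[j])
            available[j] = False
    matches = []
    p1_by_id = {s.sighting_id: s for s in p1}
    p2_by_id = {s.sighting_id: s for s in p2}
    for fid, cid in matched.items():
        matches.append((fid, cid, sighting_separation(p1_by_id[fid], p2_by_id[cid])))
    matches.sort(key=lambda m: p1_by_id[m[0]].time)
    result = DuplicateResult(matches, _build_unique_table(p1, p2, matched), thr)
    assert len(result.unique_table) == len(p1) + len(p2) - len(matches)
    return result


def brute_force_oracle(p1: list[Sighting], p2: list[Sighting],
                       thr: DuplicateThresholds | None = None) -> DuplicateResult:
    """Plain-Python re-implementation of the tree, used as a test oracle.

    Walks the focal sightings in time order; for each one it scans every
    remaining candidate with the predicate written out step by step and
    picks the closest admissible one.
    """
    thr = thr or DuplicateThresholds()
    _check_ids(p1 + p2)
    if len(p1) > 100 or len(p2) > 100:
        raise ValueError("oracle restricted to <= 100 sightings per platform")
    pool = list(p2)
    matched: dict[str, str] = {}
    for focal in sorted(p1, key=lambda s: (s.time, s.sighting_id)):
        best = None
        for cand in pool:
            sep = sighting_separation(focal, cand)
            if not _admissible(focal, cand, thr, sep):
                continue
            key = (sep, cand.time, cand.sighting_id)
            if best is None or key < best[0]:
                best = (key, cand)
        if best is not None:
            cand = best[1]
            matched[focal.sighting_id] = cand.sighting_id
            pool.remove(cand)
    matches = [
        (fid, cid, sighting_separation(
            next(s for s in p1 if s.sighting_id == fid),
            next(s for s in p2 if s.sighting_id == cid)))
        for fid, cid in matched.items()
    ]
    matches.sort(key=lambda m: next(s for s in p1 if s.sighting_id == m[0]).time)
    return DuplicateResult(matches, _build_unique_table(p1, p2, matched), thr)


def sensitivity_sweep(p1: list[Sighting], p2: list[Sighting],
                      windows: list[float],
                      base: DuplicateThresholds | None = None) -> pd.DataFrame:
    """Re-run the tree for several angle windows (e.g. 5, 15, 25 deg).

    Returns one row per window with the number of matches, the number of
    unique sightings and the platform-only fractions.
    """
    if not windows:
        raise ValueError("windows must be non-empty")
    base = base or DuplicateThresholds()
    rows = []
    for w in windows:
        thr = DuplicateThresholds(base.buffer_radius, w, base.under_plane)
        res = find_duplicates(p1, p2, thr)
        n_unique = len(res.unique_table)
        both = res.n_matches
        rows.append(
            {
                "angle_window": w,
                "n_matches": both,
                "n_unique": n_unique,
                "frac_both": both / n_unique if n_unique else np.nan,
                "frac_p1_only": (len(p1) - both) / n_unique if n_unique else np.nan,
                "frac_p2_only": (len(p2) - both) / n_unique if n_unique else np.nan,
            }
        )
    return pd.DataFrame(rows)
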