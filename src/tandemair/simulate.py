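"""Synthetic paired-platform aerial surveys with known ground truth.

The generator emulates a zig-zag aerial survey flown by two simultaneous
observation platforms. Cetacean groups follow a Thomas cluster process;
seabirds are inshore-skewed strip-transect targets recorded by the
rearward platform only; anthropogenic objects and other marine fauna are
strip targets seen by both platforms. Detection of cetacean groups is a
two-stage process: a shared distance-based half-normal "opportunity"
(availability is assumed identical between platforms) followed by
platform-specific logit-linear perception whose covariates are that
platform's own sightings in the preceding 30 s. Recording error adds GPS
jitter, an along-track recording delay and inclinometer noise.

Every random draw flows from the single ``seed`` in the configuration,
so identical configurations reproduce identical surveys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from tandemair.core import (
    Category,
    EffortLeg,
    Platform,
    Sighting,
    Subjective,
    SurveyConstants,
    distance_to_angle,
)

__all__ = [
    "SpeciesConfig",
    "SimulationConfig",
    "GroundTruth",
    "SurveyData",
    "simulate_transects",
    "simulate_groups",
    "simulate_detections",
    "simulate_survey",
]

PLATFORMS = (Platform.SCANS, Platform.MEGAFAUNA)

COVARIATE_CATEGORIES = (
    Category.CETACEAN,
    Category.OTHER_MARINE_FAUNA,
    Category.ANTHROPOGENIC,
    Category.SEABIRD_FLYING,
    Category.SEABIRD_RESTING,
    Category.SEABIRD_GROUP,
)


@dataclass(frozen=True)
class SpeciesConfig:
    """Spatial and detection parameters for one small-cetacean species."""

    name: str
    density: float  # groups / km^2
    mean_cluster_size: float = 4.0  # mean offspring groups per parent
    cluster_scale: float = 2000.0  # m, Gaussian offspring dispersion
    group_size_mean: float = 3.0  # zero-truncated Poisson rate
    sigma_scans: float = 200.0  # m, half-normal opportunity scale
    sigma_mega: float = 200.0

    def sigma(self, platform: Platform) -> float:
        return self.sigma_scans if platform == Platform.SCANS else self.sigma_mega


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic survey."""

    region_width_km: float = 100.0
    region_height_km: float = 60.0
    n_transects: int = 10
    species: tuple[SpeciesConfig, ...] = (
        SpeciesConfig("harbour_porpoise", density=0.02, sigma_scans=180.0, sigma_mega=170.0),
        SpeciesConfig("common_dolphin", density=0.03, group_size_mean=5.0,
                      sigma_scans=240.0, sigma_mega=230.0),
    )
    # logit-scale perception baselines and covariate effects per platform
    baseline_logit_p: dict = field(
        default_factory=lambda: {Platform.SCANS: 0.0, Platform.MEGAFAUNA: 0.5}
    )
    covariate_effects: dict = field(default_factory=dict)  # {(platform, Category): beta}
    # strip targets (points per km of transect)
    seabird_rate_per_km: float = 0.5
    seabird_inshore_k: float = 0.03  # per km offshore; intensity ~ exp(-k * offshore)
    anthropogenic_rate_per_km: float = 0.3
    other_fauna_rate_per_km: float = 0.1
    seabird_group_frac: float = 0.1  # fraction of seabird points that are flocks > 10
    seabird_flying_frac: float = 0.6
    # recording error
    gps_jitter_sd: float = 100.0  # m, <= 250 (half the 500 m buffer)
    recording_delay_max: float = 100.0  # m along track
    angle_noise_sd: float = 2.0  # degrees
    # geometry / protocol
    opportunity_truncation: float = 700.0  # m, max perp distance for cetacean opportunity
    negbin_dispersion: float | None = None  # group sizes: None -> zero-trunc Poisson
    leg_target_km: float = 25.0
    platform_lag_s: float = 3.0
    endpoint_trim_km: float = 0.2  # independent per-platform trim at survey ends
    sea_state_probs: tuple[float, ...] = (0.05, 0.15, 0.3, 0.25, 0.15, 0.07, 0.03)
    subjective_probs: tuple[float, ...] = (0.1, 0.3, 0.4, 0.2)  # poor..excellent
    constants: SurveyConstants = SurveyConstants()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_width_km <= 0 or self.region_height_km <= 0:
            raise ValueError("degenerate region")
        if self.n_transects < 1:
            raise ValueError("need at least one transect")
        if self.gps_jitter_sd < 0 or self.gps_jitter_sd > 250.0:
            raise ValueError("gps_jitter_sd must lie in [0, 250] m")
        if self.recording_delay_max < 0 or self.recording_delay_max > 100.0:
            raise ValueError("recording_delay_max must lie in [0, 100] m")
        if self.angle_noise_sd < 0:
            raise ValueError("angle_noise_sd must be >= 0")
        for sp in self.species:
            if sp.density < 0 or sp.cluster_scale < 0 or sp.group_size_mean <= 0:
                raise ValueError(f"invalid species config {sp.name}")

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        """Build from plain key/value data (e.g. parsed YAML): species as
        a list of dicts, platform-keyed maps keyed by platform name, and
        covariate effects keyed "PLATFORM:category"."""
        raw = dict(raw)
        if "species" in raw:
            raw["species"] = tuple(
                sp if isinstance(sp, SpeciesConfig) else SpeciesConfig(**sp)
                for sp in raw["species"]
            )
        if "baseline_logit_p" in raw:
            raw["baseline_logit_p"] = {
                Platform(k): float(v) for k, v in raw["baseline_logit_p"].items()
            }
        if "covariate_effects" in raw:
            eff = {}
            for key, v in raw["covariate_effects"].items():
                if isinstance(key, tuple):
                    plat, cat = key
                else:
                    plat, cat = key.split(":", 1)
                eff[(Platform(plat), Category(cat))] = float(v)
            raw["covariate_effects"] = eff
        return cls(**raw)


@dataclass
class TrueGroup:
    group_id: int
    species: str
    x: float
    y: float
    size: int


@dataclass
class Opportunity:
    """One cetacean group within opportunity range of a transect."""

    group_id: int
    transect_id: str
    along_m: float  # along-track distance from survey start, m
    perp_m: float
    side: str
    species: str
    size: int
    x: float
    y: float
    # filled during detection simulation, keyed by platform
    opportunity: dict = field(default_factory=dict)
    perceived: dict = field(default_factory=dict)
    true_p: dict = field(default_factory=dict)
    sighting_ids: dict = field(default_factory=dict)


@dataclass
class GroundTruth:
    groups: list[TrueGroup]
    opportunities: list[Opportunity]
    true_duplicates: list[tuple[str, str]]  # (scans sighting_id, mega sighting_id)
    true_density: dict  # species -> groups/km^2

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for op in self.opportunities:
            rows.append(
                {
                    "group_id": op.group_id,
                    "species": op.species,
                    "perp_m": op.perp_m,
                    "opportunity_scans": int(op.opportunity.get(Platform.SCANS, False)),
                    "opportunity_mega": int(op.opportunity.get(Platform.MEGAFAUNA, False)),
                    "perceived_scans": int(op.perceived.get(Platform.SCANS, False)),
                    "perceived_mega": int(op.perceived.get(Platform.MEGAFAUNA, False)),
                    "true_p_scans": op.true_p.get(Platform.SCANS, np.nan),
                    "true_p_mega": op.true_p.get(Platform.MEGAFAUNA, np.nan),
                    "sighting_id_scans": op.sighting_ids.get(Platform.SCANS, ""),
                    "sighting_id_mega": op.sighting_ids.get(Platform.MEGAFAUNA, ""),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class SurveyData:
    """The full output bundle of one simulated survey."""

    config: SimulationConfig
    transects: list[dict]
    legs: dict  # Platform -> list[EffortLeg]
    sightings: dict  # Platform -> list[Sighting]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# transects and effort


def _zigzag_vertices(cfg: SimulationConfig) -> np.ndarray:
    """Vertices (m) of the zig-zag path across the region."""
    w = cfg.region_width_km * 1000.0
    h = cfg.region_height_km * 1000.0
    xs = np.linspace(0.0, w, cfg.n_transects + 1)
    ys = np.where(np.arange(cfg.n_transects + 1) % 2 == 0, 0.0, h)
    return np.column_stack([xs, ys])


def simulate_transects(cfg: SimulationConfig, rng: np.random.Generator | None = None):
    """Build the zig-zag transect set and per-platform effort legs.

    Both platforms fly the same geometry; they differ by a small
    per-platform start-time lag and an independent trim of up to
    ``endpoint_trim_km`` at the very start and end of the survey, so
    total effort differs by well under 1%. Conditions are drawn per leg
    and shared between platforms (same aircraft, same sea).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    verts = _zigzag_vertices(cfg)
    speed_ms = cfg.constants.speed_ms

    transects = []
    cum_m = 0.0
    for i in range(cfg.n_transects):
        p0, p1 = verts[i], verts[i + 1]
        length_m = float(np.hypot(*(p1 - p0)))
        transects.append(
            {
                "transect_id": f"T{i:02d}",
                "x0": p0[0], "y0": p0[1], "x1": p1[0], "y1": p1[1],
                "length_m": length_m,
                "along0_m": cum_m,
            }
        )
        cum_m += length_m
    total_m = cum_m

    # leg boundaries (shared between platforms), cut inside transects
    leg_bounds = []  # (transect, along_from, along_to) in survey-along m
    for tr in transects:
        n_legs = max(1, int(round(tr["length_m"] / (cfg.leg_target_km * 1000.0))))
        edges = np.linspace(tr["along0_m"], tr["along0_m"] + tr["length_m"], n_legs + 1)
        for a, b in zip(edges[:-1], edges[1:]):
            leg_bounds.append((tr, float(a), float(b)))

    conditions = [
        (
            int(rng.choice(7, p=cfg.sea_state_probs)),
            list(Subjective)[int(rng.choice(4, p=cfg.subjective_probs))],
        )
        for _ in leg_bounds
    ]

    legs: dict = {}
    for platform in PLATFORMS:
        lag = rng.uniform(0.0, cfg.platform_lag_s)
        trim_start = rng.uniform(0.0, cfg.endpoint_trim_km * 1000.0)
        trim_end = rng.uniform(0.0, cfg.endpoint_trim_km * 1000.0)
        plat_legs = []
        for k, ((tr, a, b), (sea, subj)) in enumerate(zip(leg_bounds, conditions)):
            a_eff = max(a, trim_start)
            b_eff = min(b, total_m - trim_end)
            if b_eff - a_eff < 1.0:
                continue
            fa = (a_eff - tr["along0_m"]) / tr["length_m"]
            fb = (b_eff - tr["along0_m"]) / tr["length_m"]
            plat_legs.append(
                EffortLeg(
                    leg_id=f"{platform.value[:1]}-L{k:03d}",
                    transect_id=tr["transect_id"],
                    platform=platform,
                    t_start=a_eff / speed_ms + lag,
                    t_end=b_eff / speed_ms + lag,
                    x_start=tr["x0"] + fa * (tr["x1"] - tr["x0"]),
                    y_start=tr["y0"] + fa * (tr["y1"] - tr["y0"]),
                    x_end=tr["x0"] + fb * (tr["x1"] - tr["x0"]),
                    y_end=tr["y0"] + fb * (tr["y1"] - tr["y0"]),
                    length_km=(b_eff - a_eff) / 1000.0,
                    sea_state=sea,
                    subjective=subj,
                )
            )
        legs[platform] = plat_legs
    return transects, legs


# ---------------------------------------------------------------------------
# cetacean groups


def _zero_truncated_poisson(rng: np.random.Generator, lam: float, n: int) -> np.ndarray:
    """Inverse-cdf sampling of the zero-truncated Poisson."""
    if n == 0:
        return np.zeros(0, dtype=int)
    u = rng.uniform(math.exp(-lam), 1.0, size=n)
    # invert the untruncated cdf conditioned on k >= 1
    out = np.ones(n, dtype=int)
    cdf = np.full(n, math.exp(-lam))
    pmf = np.full(n, math.exp(-lam))
    k = 0
    active = np.ones(n, dtype=bool)
    while active.any() and k < 10_000:
        k += 1
        pmf = pmf * lam / k
        cdf = cdf + pmf
        done = active & (u <= cdf)
        out[done] = k
        active &= ~done
    out[active] = k
    return out


def _group_sizes(rng: np.random.Generator, sp: SpeciesConfig, n: int,
                 negbin_dispersion: float | None) -> np.ndarray:
    if negbin_dispersion is None:
        return _zero_truncated_poisson(rng, sp.group_size_mean, n)
    # zero-truncated negative binomial via rejection
    r = negbin_dispersion
    p = r / (r + sp.group_size_mean)
    sizes = np.zeros(n, dtype=int)
    todo = np.arange(n)
    while todo.size:
        draw = rng.negative_binomial(r, p, size=todo.size)
        ok = draw > 0
        sizes[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return sizes


def simulate_groups(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> list[TrueGroup]:
    """Draw true cetacean groups from a Thomas cluster process.

    Parents are Poisson with intensity density/mean_cluster_size on the
    region buffered by 5 cluster scales (so the retained intensity is
    edge-effect free); offspring are Gaussian around their parent and
    kept if inside the region. The expected number of groups in the
    region is exactly density x area.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    w = cfg.region_width_km * 1000.0
    h = cfg.region_height_km * 1000.0
    groups: list[TrueGroup] = []
    gid = 0
    for sp in cfg.species:
        if sp.density <= 0:
            continue
        margin = 5.0 * sp.cluster_scale
        area_km2 = (w + 2 * margin) * (h + 2 * margin) / 1e6
        kappa = sp.density / sp.mean_cluster_size  # parents per km^2
        n_parents = rng.poisson(kappa * area_km2)
        px = rng.uniform(-margin, w + margin, n_parents)
        py = rng.uniform(-margin, h + margin, n_parents)
        n_off = rng.poisson(sp.mean_cluster_size, n_parents)
        ox = np.repeat(px, n_off) + rng.normal(0.0, sp.cluster_scale or 1e-12, n_off.sum())
        oy = np.repeat(py, n_off) + rng.normal(0.0, sp.cluster_scale or 1e-12, n_off.sum())
        if sp.cluster_scale == 0:
            ox = np.repeat(px, n_off)
            oy = np.repeat(py, n_off)
        keep = (ox >= 0) & (ox <= w) & (oy >= 0) & (oy <= h)
        ox, oy = ox[keep], oy[keep]
        sizes = _group_sizes(rng, sp, ox.size, cfg.negbin_dispersion)
        for x, y, s in zip(ox, oy, sizes):
            groups.append(TrueGroup(gid, sp.name, float(x), float(y), int(s)))
            gid += 1
    return groups


# ---------------------------------------------------------------------------
# detections


def _project_on_transects(transects: list[dict], x: float, y: float):
    """Nearest transect: returns (transect, along_survey_m, perp_m, side)."""
    best = None
    for tr in transects:
        dx, dy = tr["x1"] - tr["x0"], tr["y1"] - tr["y0"]
        L = tr["length_m"]
        t = ((x - tr["x0"]) * dx + (y - tr["y0"]) * dy) / (L * L)
        if t < 0.0 or t > 1.0:
            continue
        # signed cross product: positive = left of flight direction
        cross = dx * (y - tr["y0"]) - dy * (x - tr["x0"])
        perp = abs(cross) / L
        if best is None or perp < best[2]:
            side = "L" if cross > 0 else "R"
            best = (tr, tr["along0_m"] + t * L, perp, side)
    return best


def _leg_for_time(legs: list[EffortLeg], t: float) -> EffortLeg | None:
    for leg in legs:
        if leg.t_start <= t <= leg.t_end:
            return leg
    return None


def _strip_points(rng, transects, rate_per_km, half_width_m, inshore_k=0.0):
    """Poisson points in a strip around each transect; inshore thinning
    uses the distance (km) from the y=0 edge as 'offshore distance'."""
    pts = []
    for tr in transects:
        lam = rate_per_km * tr["length_m"] / 1000.0
        n = rng.poisson(lam)
        t = rng.uniform(0.0, 1.0, n)
        offset = rng.uniform(-half_width_m, half_width_m, n)
        dx, dy = tr["x1"] - tr["x0"], tr["y1"] - tr["y0"]
        L = tr["length_m"]
        ux, uy = dx / L, dy / L
        nx, ny = -uy, ux
        for ti, oi in zip(t, offset):
            x = tr["x0"] + ti * dx + oi * nx
            y = tr["y0"] + ti * dy + oi * ny
            if inshore_k > 0.0:
                offshore_km = y / 1000.0
                if rng.uniform() > math.exp(-inshore_k * max(offshore_km, 0.0)):
                    continue
            pts.append((tr, tr["along0_m"] + ti * L, abs(oi), "L" if oi > 0 else "R", x, y))
    return pts


def _expit(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


def simulate_detections(
    transects: list[dict],
    legs: dict,
    groups: list[TrueGroup],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict, GroundTruth]:
    """Simulate both platforms' sighting tables plus ground truth.

    Stage 1 (opportunity): a group at perpendicular distance d is
    available to platform l with probability exp(-d^2 / (2 sigma_l^2));
    a single shared uniform draw per group drives both platforms, so
    with equal scales the opportunity set is identical (shared
    availability). Stage 2 (perception): sequential in time along the
    track, each platform perceives an opportunity with logit-linear
    probability whose covariates indicate that platform's own recorded
    sightings in the preceding ``lookback`` seconds on the same leg.
    Recording then adds GPS jitter, an along-track delay uniform on
    [0, recording_delay_max] and Gaussian angle noise.
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    consts = cfg.constants
    speed_ms = consts.speed_ms
    sp_by_name = {sp.name: sp for sp in cfg.species}

    # --- opportunities from true groups
    opportunities: list[Opportunity] = []
    for g in groups:
        proj = _project_on_transects(transects, g.x, g.y)
        if proj is None:
            continue
        tr, along, perp, side = proj
        if perp > cfg.opportunity_truncation:
            continue
        opportunities.append(
            Opportunity(g.group_id, tr["transect_id"], along, perp, side,
                        g.species, g.size, g.x, g.y)
        )
    opportunities.sort(key=lambda o: o.along_m)

    u_shared = rng.uniform(0.0, 1.0, len(opportunities))
    for op, u in zip(opportunities, u_shared):
        sp = sp_by_name[op.species]
        for platform in PLATFORMS:
            s = sp.sigma(platform)
            gd = math.exp(-op.perp_m**2 / (2.0 * s * s)) if s > 0 else 0.0
            op.opportunity[platform] = bool(u < gd)

    # --- strip targets (recorded deterministically inside their strip)
    strip_events = []  # (along_m, category, species, size, perp, side, x, y, platforms)
    seabirds = _strip_points(rng, transects, cfg.seabird_rate_per_km,
                             consts.seabird_strip, cfg.seabird_inshore_k)
    for tr, along, perp, side, x, y in seabirds:
        r = rng.uniform()
        if r < cfg.seabird_group_frac:
            cat, size = Category.SEABIRD_GROUP, 11 + int(rng.poisson(8))
        elif r < cfg.seabird_group_frac + cfg.seabird_flying_frac:
            cat, size = Category.SEABIRD_FLYING, 1 + int(rng.poisson(0.5))
        else:
            cat, size = Category.SEABIRD_RESTING, 1 + int(rng.poisson(0.5))
        strip_events.append((along, cat, "seabird", size, perp, side, x, y,
                             (Platform.MEGAFAUNA,)))
    for tr, along, perp, side, x, y in _strip_points(
            rng, transects, cfg.anthropogenic_rate_per_km, consts.boat_strip):
        strip_events.append((along, Category.ANTHROPOGENIC, "litter_or_boat", 1,
                             perp, side, x, y, PLATFORMS))
    for tr, along, perp, side, x, y in _strip_points(
            rng, transects, cfg.other_fauna_rate_per_km, consts.boat_strip):
        strip_events.append((along, Category.OTHER_MARINE_FAUNA, "fish_or_turtle", 1,
                             perp, side, x, y, PLATFORMS))

    # --- merge into one along-track event stream
    events = [("strip",) + ev for ev in strip_events] + [
        ("cetacean", op.along_m, Category.CETACEAN, op.species, op.size,
         op.perp_m, op.side, op.x, op.y, PLATFORMS, op)
        for op in opportunities
    ]
    events.sort(key=lambda e: e[1])

    sightings: dict = {p: [] for p in PLATFORMS}
    # rolling per-platform log of recorded sightings: (time, leg_id, category)
    recent: dict = {p: [] for p in PLATFORMS}
    counter = {p: 0 for p in PLATFORMS}

    # time of an along-track point for a platform = along/speed + platform lag;
    # derive lag from the first leg (along-position consistent with timing)
    plat_lag = {}
    for p in PLATFORMS:
        if legs[p]:
            leg0 = legs[p][0]
            along0 = math.hypot(leg0.x_start, leg0.y_start)  # start trim offset
            plat_lag[p] = leg0.t_start - along0 / speed_ms
        else:
            plat_lag[p] = 0.0

    def record(platform, t, leg, cat, species, size, x, y, perp, side):
        """Apply recording error and append a Sighting; returns it."""
        counter[platform] += 1
        sid = f"{platform.value[:1]}{counter[platform]:05d}"
        delay = rng.uniform(0.0, cfg.recording_delay_max) if cfg.recording_delay_max > 0 else 0.0
        jx, jy = rng.normal(0.0, cfg.gps_jitter_sd, 2) if cfg.gps_jitter_sd > 0 else (0.0, 0.0)
        # delay moves the recorded point forward along the flight direction
        dxl = (leg.x_end - leg.x_start) / (leg.length_km * 1000.0)
        dyl = (leg.y_end - leg.y_start) / (leg.length_km * 1000.0)
        true_angle = distance_to_angle(perp, consts.altitude)
        angle = true_angle + (rng.normal(0.0, cfg.angle_noise_sd) if cfg.angle_noise_sd > 0 else 0.0)
        angle = float(min(90.0, max(1e-6, angle)))
        s = Sighting(
            sighting_id=sid,
            platform=platform,
            time=t,
            x=x + jx + delay * dxl,
            y=y + jy + delay * dyl,
            side=side,
            angle=angle,
            category=cat,
            species=species,
            group_size=size,
        )
        sightings[platform].append(s)
        recent[platform].append((t, leg.leg_id, cat))
        return s

    for ev in events:
        kind = ev[0]
        along = ev[1]
        for platform in PLATFORMS:
            t = along / speed_ms + plat_lag[platform]
            leg = _leg_for_time(legs[platform], t)
            if leg is None:
                continue  # outside this platform's effort (trimmed ends)
            if kind == "strip":
                _, _, cat, species, size, perp, side, x, y, plats = ev
                if platform not in plats:
                    continue
                record(platform, t, leg, cat, species, size, x, y, perp, side)
            else:
                op: Opportunity = ev[10]
                if not op.opportunity[platform]:
                    continue
                # covariates: own recorded sightings within lookback on same leg
                z = cfg.baseline_logit_p.get(platform, 0.0)
                window = [r for r in recent[platform]
                          if t - consts.lookback <= r[0] < t and r[1] == leg.leg_id]
                present = {c for (_, _, c) in window}
                for cat in present:
                    z += cfg.covariate_effects.get((platform, cat), 0.0)
                p = _expit(z)
                op.true_p[platform] = p
                if rng.uniform() < p:
                    op.perceived[platform] = True
                    s = record(platform, t, leg, Category.CETACEAN, op.species,
                               op.size, op.x, op.y, op.perp_m, op.side)
                    op.sighting_ids[platform] = s.sighting_id
                else:
                    op.perceived[platform] = False

    true_duplicates = [
        (op.sighting_ids[Platform.SCANS], op.sighting_ids[Platform.MEGAFAUNA])
        for op in opportunities
        if Platform.SCANS in op.sighting_ids and Platform.MEGAFAUNA in op.sighting_ids
    ]
    truth = GroundTruth(
        groups=groups,
        opportunities=opportunities,
        true_duplicates=true_duplicates,
        true_density={sp.name: sp.density for sp in cfg.species},
    )
    return sightings, truth


def simulate_survey(cfg: SimulationConfig) -> SurveyData:
    """Run the full generator: transects -> groups -> detections."""
    rng = np.random.default_rng(cfg.seed)
    transects, legs = simulate_transects(cfg, rng)
    groups = simulate_groups(cfg, rng)
    sightings, truth = simulate_detections(transects, legs, groups, cfg, rng)
    return SurveyData(config=cfg, transects=transects, legs=legs,
                      sightings=sightings, truth=truth)
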