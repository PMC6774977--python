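"""CSV schemas, run configuration and the end-to-end pipeline.

All tabular files are comma-separated UTF-8 with "." decimals; model
summaries and the run manifest are JSON. Every output directory gets a
``manifest.json`` recording the seed, the configuration hash and the
files written, so a rerun with the same configuration is reproducible
byte for byte (stochastic stages are driven entirely by the seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tandemair.core import (
    Category,
    EffortLeg,
    Platform,
    Sighting,
    Subjective,
    cut_segments,
    pair_segments,
)

logger = logging.getLogger("tandemair")

EFFORT_COLUMNS = ["leg_id", "transect_id", "platform", "t_start", "t_end",
                  "x_start", "y_start", "x_end", "y_end", "length_km",
                  "sea_state", "subjective"]
SIGHTING_COLUMNS = ["sighting_id", "platform", "time_s", "x", "y", "side",
                    "angle_deg", "category", "species", "group_size"]


@dataclass
class ValidationReport:
    n_rows: int
    n_accepted: int
    rejected: list = field(default_factory=list)  # (row index, reason)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    effort_path: Path | None = None
    sightings_path: Path | None = None
    simulate: bool = True
    sim_overrides: dict = field(default_factory=dict)
    buffer_radius: float = 500.0
    angle_window: float = 15.0
    under_plane: float = 85.0
    lookback: float = 30.0
    truncation_m: float = 500.0
    condition_filter: bool = True
    cds_key: str = "auto"  # auto | hn | hr
    merge_short_km: float = 5.0  # poststrat: merge shorter segments; 0 = off
    hier_chains: int = 4
    hier_warmup: int = 1000
    hier_iter: int = 1000
    hier_thin: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw["outdir"] = Path(raw.get("outdir", "tandemair_out"))
        for key in ("effort_path", "sightings_path"):
            if raw.get(key):
                p = Path(raw[key])
                if not p.exists():
                    raise FileNotFoundError(f"{key}: {p} does not exist")
                raw[key] = p
        return cls(**raw)

    def hash(self) -> str:
        # outdir is excluded: it does not influence any analysis result
        payload = {k: str(v) for k, v in sorted(self.__dict__.items())
                   if k != "outdir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# readers / writers


def write_effort(legs: dict, path: str | Path) -> None:
    rows = []
    for platform, plist in legs.items():
        for leg in plist:
            rows.append({
                "leg_id": leg.leg_id, "transect_id": leg.transect_id,
                "platform": Platform(platform).value,
                "t_start": leg.t_start, "t_end": leg.t_end,
                "x_start": leg.x_start, "y_start": leg.y_start,
                "x_end": leg.x_end, "y_end": leg.y_end,
                "length_km": leg.length_km, "sea_state": leg.sea_state,
                "subjective": Subjective(leg.subjective).value,
            })
    pd.DataFrame(rows, columns=EFFORT_COLUMNS).to_csv(path, index=False)


def write_sightings(sightings: dict, path: str | Path) -> None:
    rows = []
    for platform, slist in sightings.items():
        for s in slist:
            rows.append({
                "sighting_id": s.sighting_id, "platform": Platform(platform).value,
                "time_s": s.time, "x": s.x, "y": s.y, "side": s.side,
                "angle_deg": s.angle, "category": Category(s.category).value,
                "species": s.species, "group_size": s.group_size,
            })
    pd.DataFrame(rows, columns=SIGHTING_COLUMNS).to_csv(path, index=False)


def _require_columns(df: pd.DataFrame, needed: list, what: str) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing column(s) {missing}")


def read_effort(path: str | Path) -> tuple[dict, ValidationReport]:
    df = pd.read_csv(path, comment="#")
    _require_columns(df, EFFORT_COLUMNS, "effort CSV")
    legs: dict = {Platform.SCANS: [], Platform.MEGAFAUNA: []}
    rejected = []
    for i, row in df.iterrows():
        try:
            leg = EffortLeg(
                leg_id=str(row.leg_id), transect_id=str(row.transect_id),
                platform=Platform(row.platform),
                t_start=float(row.t_start), t_end=float(row.t_end),
                x_start=float(row.x_start), y_start=float(row.y_start),
                x_end=float(row.x_end), y_end=float(row.y_end),
                length_km=float(row.length_km), sea_state=int(row.sea_state),
                subjective=Subjective(row.subjective),
            )
            legs[leg.platform].append(leg)
        except (ValueError, KeyError) as exc:
            rejected.append((int(i), str(exc)))
    report = ValidationReport(len(df), len(df) - len(rejected), rejected)
    for reason in rejected:
        logger.info("effort row rejected: %s", reason)
    return legs, report


def read_sightings(path: str | Path) -> tuple[dict, ValidationReport]:
    df = pd.read_csv(path, comment="#")
    _require_columns(df, SIGHTING_COLUMNS, "sightings CSV")
    sightings: dict = {Platform.SCANS: [], Platform.MEGAFAUNA: []}
    rejected = []
    for i, row in df.iterrows():
        try:
            s = Sighting(
                sighting_id=str(row.sighting_id), platform=Platform(row.platform),
                time=float(row.time_s), x=float(row.x), y=float(row.y),
                side=str(row.side), angle=float(row.angle_deg),
                category=Category(row.category), species=str(row.species),
                group_size=int(row.group_size),
            )
            sightings[s.platform].append(s)
        except (ValueError, KeyError) as exc:
            rejected.append((int(i), str(exc)))
    report = ValidationReport(len(df), len(df) - len(rejected), rejected)
    for reason in rejected:
        logger.info("sighting row rejected: %s", reason)
    return sightings, report


def read_survey(effort_path, sightings_path):
    """Read and validate both survey tables; returns (legs, sightings,
    reports)."""
    legs, rep_e = read_effort(effort_path)
    sightings, rep_s = read_sightings(sightings_path)
    return legs, sightings, {"effort": rep_e, "sightings": rep_s}


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> duplicates -> perception -> cds -> poststrat
    -> hier in order, writing each stage's outputs plus a manifest.

    A stage failure aborts with the stage name while preserving partial
    outputs.
    """
    from tandemair import cds as cds_mod
    from tandemair import hier as hier_mod
    from tandemair import poststrat as ps_mod
    from tandemair.duplicates import DuplicateThresholds, find_duplicates
    from tandemair.perception import (
        COVARIATE_NAMES,
        build_covariates,
        compare_models,
        histories_to_frame,
        predict_p,
    )
    from tandemair.simulate import SimulationConfig, simulate_survey

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config_hash": config.hash(),
                      "stages": {}, "package_version": _version()}
    stage = "simulate"
    try:
        if config.simulate:
            sim_cfg = SimulationConfig.from_dict(
                {"seed": config.seed, **config.sim_overrides})
            survey = simulate_survey(sim_cfg)
            legs, sightings = survey.legs, survey.sightings
            write_effort(legs, out / "effort.csv")
            write_sightings(sightings, out / "sightings.csv")
            survey.truth.to_frame().to_csv(out / "ground_truth.csv", index=False)
            manifest["stages"]["simulate"] = {
                "outputs": ["effort.csv", "sightings.csv", "ground_truth.csv"]}
        else:
            legs, sightings, _ = read_survey(config.effort_path, config.sightings_path)
            manifest["stages"]["simulate"] = {"outputs": [], "skipped": True}
        logger.info("stage simulate done (%d + %d sightings)",
                    len(sightings[Platform.SCANS]), len(sightings[Platform.MEGAFAUNA]))

        stage = "duplicates"
        thr = DuplicateThresholds(config.buffer_radius, config.angle_window,
                                  config.under_plane)
        cet = {p: [s for s in v if s.category == Category.CETACEAN]
               for p, v in sightings.items()}
        dup = find_duplicates(cet[Platform.SCANS], cet[Platform.MEGAFAUNA], thr)
        pd.DataFrame(dup.matches, columns=["id_p1", "id_p2", "separation_m"]).to_csv(
            out / "duplicates.csv", index=False)
        dup.unique_table.to_csv(out / "unique_table.csv", index=False)
        manifest["stages"]["duplicates"] = {
            "outputs": ["duplicates.csv", "unique_table.csv"],
            "n_matches": dup.n_matches}

        stage = "perception"
        histories = build_covariates(dup.unique_table, sightings, legs,
                                     lookback=config.lookback)
        histories_to_frame(histories).to_csv(out / "histories.csv", index=False)
        ranking = compare_models(histories)
        ranking.drop(columns=[], errors="ignore").to_csv(
            out / "perception_models.csv", index=False)
        best = ranking.attrs["fits"][ranking["formula"].iloc[0]]
        best.summary().to_csv(out / "perception_coefficients.csv")
        pred_rows = []
        for platform in (Platform.SCANS, Platform.MEGAFAUNA):
            for profile_name, profile in [("baseline", {})] + [
                    (name, {name: 1}) for name in COVARIATE_NAMES]:
                pv, (lo, hi) = predict_p(best, platform, profile)
                pred_rows.append({"platform": platform.value,
                                  "profile": profile_name, "p": pv,
                                  "ci_low": lo, "ci_high": hi})
        pd.DataFrame(pred_rows).to_csv(out / "perception_predictions.csv",
                                       index=False)
        manifest["stages"]["perception"] = {
            "outputs": ["histories.csv", "perception_models.csv",
                        "perception_coefficients.csv",
                        "perception_predictions.csv"],
            "best": ranking["formula"].iloc[0]}

        stage = "cds"
        fits = []
        densities = []
        for platform in (Platform.SCANS, Platform.MEGAFAUNA):
            flegs, fsight = cds_mod.filter_conditions(
                legs[platform], cet[platform], bypass=not config.condition_filter)
            d = [s.perp_distance() for s in fsight]
            if config.cds_key == "auto":
                fit = cds_mod.select_key(d, config.truncation_m)
            else:
                key = {"hn": "half_normal", "hr": "hazard_rate"}[config.cds_key]
                fit = cds_mod.fit_detection(d, key, config.truncation_m)
            est = cds_mod.estimate_density(flegs, fsight, fit)
            fits.append({"platform": platform.value, "key": fit.key,
                         "sigma_m": fit.sigma, "shape": fit.shape,
                         "esw_m": fit.esw, "esw_cv": fit.esw_cv, "aic": fit.aic,
                         "n": fit.n_sightings})
            densities.append({"platform": platform.value, "density": est.density,
                              "cv": est.cv, "ci_low": est.ci_low,
                              "ci_high": est.ci_high,
                              "encounter_rate": est.encounter_rate,
                              "effort_km": est.effort_km})
        pd.DataFrame(fits).to_csv(out / "cds_fits.csv", index=False)
        pd.DataFrame(densities).to_csv(out / "cds_density.csv", index=False)
        manifest["stages"]["cds"] = {
            "outputs": ["cds_fits.csv", "cds_density.csv"]}

        stage = "poststrat"
        segments = {p: ps_mod.merge_short_segments(cut_segments(legs[p]),
                                                    config.merge_short_km)
                    for p in (Platform.SCANS, Platform.MEGAFAUNA)}
        pairs, _, _ = pair_segments(segments[Platform.SCANS], segments[Platform.MEGAFAUNA])
        rates = ps_mod.encounter_rates(
            sightings, {p: sum(l.length_km for l in legs[p]) for p in sightings})
        rates.to_csv(out / "encounter_rates.csv", index=False)
        diffs = ps_mod.paired_difference(pairs, sightings)
        diffs.to_csv(out / "paired_differences.csv", index=False)
        seg_m = segments[Platform.MEGAFAUNA]
        scheme_rows = []
        strat_tables = []
        for target in ("anthropogenic", "seabird", "other_fauna"):
            cats = ps_mod.TARGET_CATEGORIES[target]
            counts = ps_mod.count_on_segments(seg_m, sightings[Platform.MEGAFAUNA], cats)
            seg_rates = counts / np.array([s.length_km for s in seg_m])
            try:
                scheme = ps_mod.make_classes(seg_rates, target)
            except ValueError as exc:
                logger.warning("poststrat %s skipped: %s", target, exc)
                continue
            scheme_rows.append({"target_type": target,
                                "thresholds": list(scheme.thresholds),
                                "n_classes": scheme.n_classes})
            strat = ps_mod.stratified_cds(segments, pairs, sightings, scheme,
                                          truncation=config.truncation_m)
            plain = strat.table.copy()
            plain.attrs = {}  # attrs hold frames, which break pd.concat
            strat_tables.append(plain)
        pd.DataFrame(scheme_rows).to_csv(out / "class_schemes.csv", index=False)
        if strat_tables:
            pd.concat(strat_tables, ignore_index=True).to_csv(
                out / "stratified_estimates.csv", index=False)
        manifest["stages"]["poststrat"] = {
            "outputs": ["encounter_rates.csv", "paired_differences.csv",
                        "class_schemes.csv", "stratified_estimates.csv"]}

        stage = "hier"
        rng = np.random.default_rng(config.seed + 99)
        rows = []
        for platform in (Platform.SCANS, Platform.MEGAFAUNA):
            for s in cet[platform]:
                d_km = s.perp_distance() / 1000.0
                rows.append({"distance_km": d_km, "platform": platform.value,
                             "observer": f"obs{rng.integers(0, 3)}",
                             "species": s.species})
        df = pd.DataFrame(rows)
        truncs = {sp: config.truncation_m / 1000.0 for sp in df["species"].unique()}
        df = df[df["distance_km"] <= config.truncation_m / 1000.0]
        hdata = hier_mod.HierData.from_frame(df, truncs)
        mcfg = hier_mod.McmcConfig(config.hier_chains, config.hier_warmup,
                                   config.hier_iter, config.hier_thin,
                                   seed=config.seed)
        sample = hier_mod.sample_posterior(hdata, mcfg)
        sample.to_frame().to_csv(out / "hier_draws.csv", index=False)
        hier_mod.esw_summaries(sample).to_csv(out / "hier_esw.csv", index=False)
        sample.rhat_table().to_csv(out / "hier_rhat.csv", index=False)
        manifest["stages"]["hier"] = {
            "outputs": ["hier_draws.csv", "hier_esw.csv", "hier_rhat.csv"]}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    _stamp_outputs(out, manifest, config)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _stamp_outputs(out: Path, manifest: dict, config: RunConfig) -> None:
    """Prepend a seed/config-hash comment line to every CSV output."""
    header = f"# seed={config.seed} config_hash={config.hash()}\n"
    for stage in manifest["stages"].values():
        for name in stage.get("outputs", []):
            path = out / name
            if path.suffix == ".csv" and path.exists():
                body = path.read_text()
                if not body.startswith("# seed="):
                    path.write_text(header + body)


def _version() -> str:
    from tandemair import __version__

    return __version__
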