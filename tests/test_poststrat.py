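import numpy as np
import pytest

from tandemair.core import Category, Platform, cut_segments, pair_segments
from tandemair.poststrat import (
    ClassScheme,
    count_on_segments,
    encounter_rates,
    make_classes,
    paired_difference,
    stratified_cds,
)
from tandemair.simulate import SimulationConfig, SpeciesConfig, simulate_survey
from tests.conftest import make_sighting


class TestEncounterRates:
    def test_simple_ratio(self):
        sightings = {Platform.SCANS: [make_sighting(f"s{i}", time=float(i),
                                                    category=Category.ANTHROPOGENIC,
                                                    species="litter")
                                      for i in range(10)],
                     Platform.MEGAFAUNA: []}
        table = encounter_rates(sightings, {Platform.SCANS: 100.0,
                                            Platform.MEGAFAUNA: 100.0})
        row = table[(table.platform == "SCANS") & (table.category == "anthropogenic")]
        assert row["rate_per_km"].iloc[0] == pytest.approx(0.1)

    def test_empty_category_zero(self):
        table = encounter_rates({Platform.SCANS: [], Platform.MEGAFAUNA: []},
                                {Platform.SCANS: 50.0, Platform.MEGAFAUNA: 50.0})
        assert (table["rate_per_km"] == 0).all()

    def test_zero_effort_errors(self):
        with pytest.raises(ValueError):
            encounter_rates({Platform.SCANS: []}, {Platform.SCANS: 0.0})

    def test_seabirds_megafauna_only(self):
        table = encounter_rates({Platform.SCANS: [], Platform.MEGAFAUNA: []},
                                {Platform.SCANS: 50.0, Platform.MEGAFAUNA: 50.0})
        birds = table[table.category == "seabirds"]
        assert set(birds["platform"]) == {"MEGAFAUNA"}


def _paired_survey(seed=13):
    sv = simulate_survey(SimulationConfig(seed=seed))
    segs = {p: cut_segments(sv.legs[p]) for p in sv.legs}
    pairs, _, _ = pair_segments(segs[Platform.SCANS], segs[Platform.MEGAFAUNA])
    return sv, segs, pairs


class TestPairedDifference:
    def test_identical_platforms_zero(self):
        sv, segs, pairs = _paired_survey()
        # feed the same sightings to both platforms
        same = {Platform.SCANS: sv.sightings[Platform.MEGAFAUNA],
                Platform.MEGAFAUNA: sv.sightings[Platform.MEGAFAUNA]}
        table = paired_difference(pairs, same)
        # time pairing is near-exact so per-segment rates coincide
        assert (table["mean_diff"].abs() < 0.02).all()

    def test_no_pairs_errors(self):
        with pytest.raises(ValueError):
            paired_difference([], {})

    def test_sign_convention(self):
        sv, segs, pairs = _paired_survey()
        only_mega = {Platform.SCANS: [],
                     Platform.MEGAFAUNA: sv.sightings[Platform.MEGAFAUNA]}
        table = paired_difference(pairs, only_mega)
        anth = table[table.category == "anthropogenic"]
        assert anth["mean_diff"].iloc[0] > 0  # MEGAFAUNA minus SCANS

    def test_equal_intensity_ci_covers_zero_mostly(self):
        covered = 0
        reps = 20
        for r in range(reps):
            sv, segs, pairs = _paired_survey(seed=500 + r)
            table = paired_difference(pairs, sv.sightings)
            anth = table[table.category == "anthropogenic"].iloc[0]
            if anth["zero_in_ci"]:
                covered += 1
        assert covered >= int(0.8 * reps)


class TestMergeShortSegments:
    def test_trailing_remainder_merged(self):
        from tandemair.core import EffortLeg, Subjective
        from tandemair.poststrat import merge_short_segments

        leg = EffortLeg("L0", "T0", Platform.SCANS, 0.0, 24_000 / 46.4,
                        0.0, 0.0, 24_000.0, 0.0, 24.0, 2, Subjective.GOOD)
        segs = cut_segments([leg], 10.0)
        merged = merge_short_segments(segs, 5.0)
        assert [round(s.length_km, 6) for s in segs] == [10.0, 10.0, 4.0]
        assert [round(s.length_km, 6) for s in merged] == [10.0, 14.0]
        assert sum(s.length_km for s in merged) == pytest.approx(24.0)

    def test_disabled(self):
        from tandemair.core import EffortLeg, Subjective
        from tandemair.poststrat import merge_short_segments

        leg = EffortLeg("L0", "T0", Platform.SCANS, 0.0, 25_000 / 46.4,
                        0.0, 0.0, 25_000.0, 0.0, 25.0, 2, Subjective.GOOD)
        segs = cut_segments([leg], 10.0)
        assert merge_short_segments(segs, 0.0) == segs

    def test_never_merges_across_legs(self):
        from tandemair.core import EffortLeg, Subjective
        from tandemair.poststrat import merge_short_segments

        legs = [EffortLeg(f"L{i}", "T0", Platform.SCANS, i * 600.0,
                          i * 600.0 + 12_000 / 46.4, 0.0, 0.0, 12_000.0, 0.0,
                          12.0, 2, Subjective.GOOD) for i in range(2)]
        segs = cut_segments(legs, 10.0)
        merged = merge_short_segments(segs, 5.0)
        assert all(m.leg_id in {"L0", "L1"} for m in merged)
        assert len(merged) == 2  # 2-km tails merged within their own leg


class TestMakeClasses:
    def test_table_style_thresholds_assignment(self):
        scheme = ClassScheme("anthropogenic", (0.17, 0.30, 0.50), 5)
        assert scheme.assign(0.25) == 3  # inside [0.17; 0.30)
        assert scheme.assign(0.0) == 1
        assert scheme.assign(0.17) == 3  # left-closed
        assert scheme.assign(0.60) == 5  # >= last threshold

    def test_uniform_rates_equal_counts(self, rng):
        rates = np.concatenate([np.zeros(20), rng.uniform(0.01, 1.0, 101)])
        scheme = make_classes(rates, "anthropogenic")
        classes = np.array([scheme.assign(r) for r in rates])
        counts = [np.sum(classes == c) for c in range(2, 6)]
        assert max(counts) - min(counts) <= 1

    def test_zero_rate_always_class_1(self, rng):
        rates = rng.uniform(0.0, 1.0, 50)
        scheme = make_classes(rates, "seabird")
        assert scheme.assign(0.0) == 1

    def test_quartiles_match_independent_percentiles(self, rng):
        rates = np.concatenate([np.zeros(10), rng.gamma(2.0, 0.1, 200)])
        scheme = make_classes(rates, "anthropogenic")
        nonzero = np.sort(rates[rates > 0])
        # independent type-7 percentile computation
        for q, thr in zip((0.25, 0.50, 0.75), scheme.thresholds):
            h = (len(nonzero) - 1) * q
            lo = int(np.floor(h))
            expected = nonzero[lo] + (h - lo) * (nonzero[min(lo + 1, len(nonzero) - 1)]
                                                 - nonzero[lo])
            assert thr == pytest.approx(expected, abs=1e-12)

    def test_other_fauna_two_classes(self, rng):
        rates = np.concatenate([np.zeros(5), rng.uniform(0.01, 1.0, 10)])
        scheme = make_classes(rates, "other_fauna")
        assert scheme.n_classes == 2
        assert scheme.assign(0.0) == 1
        assert scheme.assign(0.5) == 2

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning):
            scheme = make_classes(np.zeros(10), "seabird")
        assert scheme.n_classes == 1

    def test_too_few_nonzero(self):
        with pytest.raises(ValueError):
            make_classes(np.array([0.0, 0.1, 0.2]), "seabird")


def _dense_survey(seed=17):
    cfg = SimulationConfig(
        seed=seed, region_width_km=120.0, region_height_km=80.0, n_transects=12,
        species=(SpeciesConfig("hp", density=0.25, sigma_scans=250.0,
                               sigma_mega=250.0),),
        baseline_logit_p={Platform.SCANS: 2.0, Platform.MEGAFAUNA: 2.0},
        anthropogenic_rate_per_km=0.4,
        seabird_inshore_k=0.0,
    )
    return simulate_survey(cfg)


class TestStratifiedCds:
    def test_partition_and_effort_conservation(self):
        sv = _dense_survey()
        segs = {p: cut_segments(sv.legs[p]) for p in sv.legs}
        pairs, _, _ = pair_segments(segs[Platform.SCANS], segs[Platform.MEGAFAUNA])
        seg_m = segs[Platform.MEGAFAUNA]
        counts = count_on_segments(seg_m, sv.sightings[Platform.MEGAFAUNA],
                                   {Category.ANTHROPOGENIC})
        rates = counts / np.array([s.length_km for s in seg_m])
        scheme = make_classes(rates, "anthropogenic")
        classes = np.array([scheme.assign(r) for r in rates])
        assert np.all((classes >= 1) & (classes <= 5))  # partition
        strat = stratified_cds(segs, pairs, sv.sightings, scheme)
        mega = strat.table[strat.table.platform == "MEGAFAUNA"]
        assert mega["effort_km"].sum() == pytest.approx(
            sum(s.length_km for s in seg_m), rel=1e-9)

    def test_homogeneous_classes_match_global(self):
        sv = _dense_survey(seed=19)
        segs = {p: cut_segments(sv.legs[p]) for p in sv.legs}
        pairs, _, _ = pair_segments(segs[Platform.SCANS], segs[Platform.MEGAFAUNA])
        seg_m = segs[Platform.MEGAFAUNA]
        counts = count_on_segments(seg_m, sv.sightings[Platform.MEGAFAUNA],
                                   {Category.ANTHROPOGENIC})
        rates = counts / np.array([s.length_km for s in seg_m])
        scheme = make_classes(rates, "anthropogenic")
        strat = stratified_cds(segs, pairs, sv.sightings, scheme)
        from tandemair.cds import estimate_density, fit_detection

        for platform in (Platform.MEGAFAUNA,):
            cet = [s for s in sv.sightings[platform]
                   if s.category == Category.CETACEAN]
            d = [s.perp_distance() for s in cet if s.perp_distance() <= 500.0]
            fit = fit_detection(d, "half_normal", 500.0)
            est = estimate_density(sv.legs[platform], cet, fit)
            sub = strat.table[strat.table.platform == platform.value]
            inside = ((sub["density"] >= est.ci_low * 0.8)
                      & (sub["density"] <= est.ci_high * 1.2))
            # homogeneous simulation: class densities sit near the global one
            assert inside.mean() >= 0.8

    def test_ci_overlap_between_platforms(self):
        sv = _dense_survey(seed=23)
        segs = {p: cut_segments(sv.legs[p]) for p in sv.legs}
        pairs, _, _ = pair_segments(segs[Platform.SCANS], segs[Platform.MEGAFAUNA])
        seg_m = segs[Platform.MEGAFAUNA]
        counts = count_on_segments(seg_m, sv.sightings[Platform.MEGAFAUNA],
                                   {Category.ANTHROPOGENIC})
        rates = counts / np.array([s.length_km for s in seg_m])
        scheme = make_classes(rates, "anthropogenic")
        strat = stratified_cds(segs, pairs, sv.sightings, scheme)
        overlap = strat.table.attrs["ci_overlap"]
        assert overlap["ci_overlap"].mean() >= 0.8
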