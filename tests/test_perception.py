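import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from tandemair.core import Category, EffortLeg, Platform, Subjective
from tandemair.perception import (
    COVARIATE_NAMES,
    DetectionHistory,
    build_covariates,
    compare_models,
    fit_perception,
    histories_to_frame,
    null_closed_form,
    predict_p,
)
from tests.conftest import make_sighting

ZERO_COV = {name: 0 for name in COVARIATE_NAMES}


def history(i, ys, ym, x_scans=None, x_mega=None):
    return DetectionHistory(
        f"u{i}",
        {Platform.SCANS: ys, Platform.MEGAFAUNA: ym},
        {Platform.SCANS: dict(ZERO_COV, **(x_scans or {})),
         Platform.MEGAFAUNA: dict(ZERO_COV, **(x_mega or {}))},
    )


def simulate_histories(rng, n, logit_base, betas=None, cov_prob=0.3):
    """Direct generator from the logit model (independent of the spatial
    simulator); draws are conditioned on at least one detection."""
    betas = betas or {}
    out = []
    i = 0
    while len(out) < n:
        covs = {p: {name: int(rng.uniform() < cov_prob) for name in COVARIATE_NAMES}
                for p in (Platform.SCANS, Platform.MEGAFAUNA)}
        ys = {}
        for p in (Platform.SCANS, Platform.MEGAFAUNA):
            z = logit_base[p]
            for name, v in covs[p].items():
                z += betas.get((p, name), 0.0) * v
            ys[p] = int(rng.uniform() < expit(z))
        if ys[Platform.SCANS] + ys[Platform.MEGAFAUNA] == 0:
            continue  # unique sightings are seen by at least one platform
        out.append(DetectionHistory(f"u{i}", ys, covs))
        i += 1
    return out


# ---------------------------------------------------------------------------
# covariates


def _leg(platform, t0=0.0, t1=600.0, leg_id="L0"):
    return EffortLeg(leg_id, "T0", platform, t0, t1, 0.0, 0.0,
                     (t1 - t0) * 46.4, 0.0, (t1 - t0) * 46.4 / 1000.0, 2,
                     Subjective.GOOD)


def _unique_row(uid="u0", t=100.0, y1=1, y2=0, id1="a0", id2=""):
    return pd.DataFrame([{"unique_id": uid, "y_p1": y1, "y_p2": y2, "time": t,
                          "x": 0.0, "y": 0.0, "species_p1": "hp",
                          "species_p2": "", "id_p1": id1, "id_p2": id2}])


class TestBuildCovariates:
    def _legs(self):
        return {Platform.SCANS: [_leg(Platform.SCANS)],
                Platform.MEGAFAUNA: [_leg(Platform.MEGAFAUNA)]}

    def test_empty_window_all_zero(self):
        hs = build_covariates(_unique_row(), {Platform.SCANS: [], Platform.MEGAFAUNA: []},
                              self._legs())
        assert len(hs) == 1
        assert all(v == 0 for v in hs[0].x[Platform.SCANS].values())
        assert all(v == 0 for v in hs[0].x[Platform.MEGAFAUNA].values())

    def test_seabird_proxy_applies_to_both(self):
        bird = make_sighting("m1", Platform.MEGAFAUNA, time=90.0,
                             category=Category.SEABIRD_FLYING, species="gull")
        hs = build_covariates(_unique_row(t=100.0),
                              {Platform.SCANS: [], Platform.MEGAFAUNA: [bird]},
                              self._legs())
        assert hs[0].x[Platform.MEGAFAUNA]["seabird_flying"] == 1
        assert hs[0].x[Platform.SCANS]["seabird_flying"] == 1  # proxy

    def test_seabird_group_above_ten(self):
        flock = make_sighting("m1", Platform.MEGAFAUNA, time=95.0,
                              category=Category.SEABIRD_GROUP, species="gull",
                              group_size=11)
        hs = build_covariates(_unique_row(t=100.0),
                              {Platform.SCANS: [], Platform.MEGAFAUNA: [flock]},
                              self._legs())
        assert hs[0].x[Platform.MEGAFAUNA]["seabird_group"] == 1

    def test_boundary_exactly_30s_included(self):
        cet = make_sighting("s9", Platform.SCANS, time=70.0)
        hs = build_covariates(_unique_row(t=100.0),
                              {Platform.SCANS: [cet], Platform.MEGAFAUNA: []},
                              self._legs())
        assert hs[0].x[Platform.SCANS]["cetaceans"] == 1

    def test_other_leg_never_qualifies(self):
        legs = {Platform.SCANS: [_leg(Platform.SCANS, 0.0, 95.0, "L0"),
                                 _leg(Platform.SCANS, 95.0, 600.0, "L1")],
                Platform.MEGAFAUNA: [_leg(Platform.MEGAFAUNA)]}
        cet = make_sighting("s9", Platform.SCANS, time=90.0)  # previous leg
        hs = build_covariates(_unique_row(t=100.0),
                              {Platform.SCANS: [cet], Platform.MEGAFAUNA: []}, legs)
        assert hs[0].x[Platform.SCANS]["cetaceans"] == 0

    def test_outside_any_leg_excluded(self):
        with pytest.warns(UserWarning):
            hs = build_covariates(_unique_row(t=9999.0),
                                  {Platform.SCANS: [], Platform.MEGAFAUNA: []},
                                  self._legs())
        assert hs == []

    def test_own_record_excluded(self):
        # the unique sighting's own record must not count as a prior cetacean
        cet = make_sighting("a0", Platform.SCANS, time=100.0)
        hs = build_covariates(_unique_row(t=100.0, id1="a0"),
                              {Platform.SCANS: [cet], Platform.MEGAFAUNA: []},
                              self._legs())
        assert hs[0].x[Platform.SCANS]["cetaceans"] == 0


# ---------------------------------------------------------------------------
# fitting


class TestFitPerception:
    def test_null_closed_form_reconstructed_split(self):
        hs = ([history(i, 1, 1) for i in range(387)]
              + [history(400 + i, 1, 0) for i in range(304)]
              + [history(800 + i, 0, 1) for i in range(356)])
        m = fit_perception(hs, "null")
        cf = null_closed_form(hs)
        p_s, _ = predict_p(m, Platform.SCANS)
        p_m, _ = predict_p(m, Platform.MEGAFAUNA)
        assert p_s == pytest.approx(cf[Platform.SCANS], abs=1e-6)
        assert p_m == pytest.approx(cf[Platform.MEGAFAUNA], abs=1e-6)
        assert p_s == pytest.approx(0.660, abs=5e-4)
        assert p_m == pytest.approx(0.710, abs=5e-4)

    def test_all_ones_separation(self):
        hs = [history(i, 1, 1) for i in range(50)]
        with pytest.warns(UserWarning, match="separation"):
            m = fit_perception(hs, "null")
        assert predict_p(m, Platform.SCANS)[0] > 0.999
        assert predict_p(m, Platform.MEGAFAUNA)[0] > 0.999
        assert m.separation_flags

    def test_aic_definition(self, rng):
        hs = simulate_histories(rng, 200, {Platform.SCANS: 0.3, Platform.MEGAFAUNA: 0.5})
        m = fit_perception(hs, "model1")
        assert m.aic == pytest.approx(-2 * m.loglik + 2 * m.k)

    def test_parameter_recovery(self, rng):
        base = {Platform.SCANS: logit(0.40), Platform.MEGAFAUNA: logit(0.56)}
        beta_cet = {(Platform.SCANS, "cetaceans"): logit(0.94) - logit(0.40),
                    (Platform.MEGAFAUNA, "cetaceans"): logit(0.97) - logit(0.56)}
        # histories are conditioned on >= 1 detection, so recovery of the
        # generating parameters needs the conditional-on-detection likelihood
        hs = simulate_histories(rng, 5000, base, beta_cet)
        m = fit_perception(hs, "model2", conditional=True)
        p_s, _ = predict_p(m, Platform.SCANS)
        p_m, _ = predict_p(m, Platform.MEGAFAUNA)
        p_s_cet, _ = predict_p(m, Platform.SCANS, {"cetaceans": 1})
        p_m_cet, _ = predict_p(m, Platform.MEGAFAUNA, {"cetaceans": 1})
        assert p_s == pytest.approx(0.40, abs=0.05)
        assert p_m == pytest.approx(0.56, abs=0.05)
        assert p_s_cet == pytest.approx(0.94, abs=0.03)
        assert p_m_cet == pytest.approx(0.97, abs=0.03)

    def test_mle_beats_truth_loglik(self, rng):
        from tandemair.perception import _design_matrix, _nll_unconditional

        base = {Platform.SCANS: 0.1, Platform.MEGAFAUNA: 0.4}
        betas = {(Platform.SCANS, "anthropogenic"): 0.8}
        hs = simulate_histories(rng, 800, base, betas)
        m = fit_perception(hs, "model2")
        df = histories_to_frame(hs)
        X, names = _design_matrix(df, "model2")
        truth = np.zeros(len(names))
        truth[names.index("(Intercept)")] = base[Platform.SCANS]
        truth[names.index("platform[MEGAFAUNA]")] = (base[Platform.MEGAFAUNA]
                                                    - base[Platform.SCANS])
        truth[names.index("anthropogenic")] = 0.8
        truth[names.index("platform[MEGAFAUNA]:anthropogenic")] = -0.8
        y = df["y"].to_numpy(float)
        assert -_nll_unconditional(m.coefficients, X, y) >= -_nll_unconditional(truth, X, y)

    def test_conditional_variant_runs(self, rng):
        hs = simulate_histories(rng, 400, {Platform.SCANS: 0.2, Platform.MEGAFAUNA: 0.6})
        m = fit_perception(hs, "null", conditional=True)
        m0 = fit_perception(hs, "null")
        # data are conditioned on >= 1 detection, which inflates the
        # unconditional estimate; the conditional fit corrects downward
        # toward the generating value
        truth = expit(0.2)
        p_cond = predict_p(m, Platform.SCANS)[0]
        p_unc = predict_p(m0, Platform.SCANS)[0]
        assert p_cond < p_unc
        assert abs(p_cond - truth) < abs(p_unc - truth)

    def test_empty_histories(self):
        with pytest.raises(ValueError):
            fit_perception([], "null")


class TestCompareModels:
    def test_interaction_data_prefers_model2(self, rng):
        wins = 0
        reps = 20
        base = {Platform.SCANS: logit(0.4), Platform.MEGAFAUNA: logit(0.56)}
        betas = {(Platform.SCANS, "cetaceans"): 2.5,
                 (Platform.MEGAFAUNA, "seabird_flying"): -1.5}
        for r in range(reps):
            hs = simulate_histories(np.random.default_rng(100 + r), 2000, base, betas)
            table = compare_models(hs)
            if table["formula"].iloc[0] == "model2":
                wins += 1
        assert wins >= int(0.9 * reps)

    def test_no_effect_data_keeps_null_close(self, rng):
        close = 0
        reps = 10
        for r in range(reps):
            hs = simulate_histories(np.random.default_rng(300 + r), 1000,
                                    {Platform.SCANS: 0.3, Platform.MEGAFAUNA: 0.6})
            table = compare_models(hs)
            null_aic = table.loc[table["formula"] == "null", "aic"].iloc[0]
            if null_aic - table["aic"].min() < 2.0:
                close += 1
        assert close >= reps // 2 + 1

    def test_single_model(self, rng):
        hs = simulate_histories(rng, 100, {Platform.SCANS: 0.0, Platform.MEGAFAUNA: 0.0})
        table = compare_models(hs, formulas=("null",))
        assert list(table["formula"]) == ["null"]
        assert table["delta_aic"].iloc[0] == 0.0


class TestPredict:
    def test_null_prediction_matches_fraction(self, rng):
        hs = simulate_histories(rng, 500, {Platform.SCANS: 0.4, Platform.MEGAFAUNA: 0.9})
        m = fit_perception(hs, "null")
        cf = null_closed_form(hs)
        assert predict_p(m, Platform.SCANS)[0] == pytest.approx(
            cf[Platform.SCANS], abs=1e-6)

    def test_zero_beta_profile_invariant(self, rng):
        hs = simulate_histories(rng, 500, {Platform.SCANS: 0.4, Platform.MEGAFAUNA: 0.9})
        m = fit_perception(hs, "null")  # no covariate terms at all
        p0, _ = predict_p(m, Platform.SCANS, {})
        p1, _ = predict_p(m, Platform.SCANS, {"cetaceans": 1})
        assert p0 == p1

    def test_unknown_covariate(self, rng):
        hs = simulate_histories(rng, 50, {Platform.SCANS: 0.4, Platform.MEGAFAUNA: 0.9})
        m = fit_perception(hs, "model1")
        with pytest.raises(ValueError):
            predict_p(m, Platform.SCANS, {"bogus": 1})

    def test_ci_inside_unit_interval(self, rng):
        hs = simulate_histories(rng, 200, {Platform.SCANS: 0.4, Platform.MEGAFAUNA: 0.9})
        m = fit_perception(hs, "model1")
        for profile in ({}, {"cetaceans": 1}, {"seabird_group": 1}):
            p, (lo, hi) = predict_p(m, Platform.MEGAFAUNA, profile)
            assert 0.0 < lo <= p <= hi < 1.0
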