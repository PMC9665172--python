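"""Slope design coding and the piecewise multilevel models."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from emotraj.aggregate import StudyWindow
from emotraj.mlm import (
    DEFAULT_ANCHORS,
    ModelError,
    attach_design,
    build_slope_design,
    empty_model_lrt,
    filter_min_users_per_day,
    fit_empty_model,
    fit_model,
    lrt_random_effect,
)
from emotraj.synthetic import SynthConfig, gen_person_days

FIT_WINDOW = StudyWindow(date(2020, 1, 20), date(2020, 2, 6), date(2020, 1, 23))

# hand-coded slope table for the default fitting window
HAND_DESIGN = {
    date(2020, 1, 20): (0, 0, 0, 0),
    date(2020, 1, 21): (1, 0, 0, 0),
    date(2020, 1, 22): (2, 0, 0, 0),
    date(2020, 1, 23): (2, 1, 0, 0),
    date(2020, 1, 24): (2, 1, 1, 0),
    date(2020, 1, 25): (2, 1, 1, 1),
    date(2020, 1, 26): (2, 1, 1, 2),
    date(2020, 1, 27): (2, 1, 1, 3),
    date(2020, 1, 28): (2, 1, 1, 4),
    date(2020, 1, 29): (2, 1, 1, 5),
    date(2020, 1, 30): (2, 1, 1, 6),
    date(2020, 1, 31): (2, 1, 1, 7),
    date(2020, 2, 1): (2, 1, 1, 8),
    date(2020, 2, 2): (2, 1, 1, 9),
    date(2020, 2, 3): (2, 1, 1, 10),
    date(2020, 2, 4): (2, 1, 1, 11),
    date(2020, 2, 5): (2, 1, 1, 12),
    date(2020, 2, 6): (2, 1, 1, 13),
}


class TestSlopeDesign:
    def test_full_table_matches_hand_coding_cell_by_cell(self):
        design = build_slope_design(FIT_WINDOW)
        assert len(design) == 18
        for day, expected in HAND_DESIGN.items():
            assert tuple(design.loc[day]) == expected, day

    def test_event_day_coding_examples(self):
        design = build_slope_design(FIT_WINDOW)
        assert design.loc[date(2020, 1, 25), "slope4"] == 1
        assert design.loc[date(2020, 1, 26), "slope4"] == 2

    def test_event_indicators(self):
        design = build_slope_design(FIT_WINDOW)
        for day in design.index:
            assert design.loc[day, "slope2"] == int(day >= date(2020, 1, 23))
            assert design.loc[day, "slope3"] == int(day >= date(2020, 1, 24))

    def test_unordered_anchors_rejected(self):
        bad = (date(2020, 1, 22), date(2020, 1, 20),
               date(2020, 1, 23), date(2020, 1, 24))
        with pytest.raises(ModelError, match="increasing"):
            build_slope_design(FIT_WINDOW, bad)

    def test_anchor_outside_window_rejected(self):
        with pytest.raises(ModelError):
            build_slope_design(
                StudyWindow(date(2020, 1, 21), date(2020, 2, 6), date(2020, 1, 23)),
                DEFAULT_ANCHORS,
            )


def _balanced_pdays(rng, n_users=100, n_days=8, between=1.0, within=1.0):
    rows = []
    for i in range(n_users):
        u = rng.normal(0, between)
        for d in range(n_days):
            rows.append({"user_id": f"u{i}", "date": date(2020, 1, 9 + d),
                         "valence": 0.3 + u + rng.normal(0, within)})
    return pd.DataFrame(rows)


class TestEmptyModel:
    def test_icc_recovers_generating_ratio(self):
        cfg = SynthConfig(
            seed=11, n_wuhan=0, n_non_hubei=500, model="empty",
            p_post_day=1.0, dataset2=False,
            window=StudyWindow(date(2020, 1, 9), date(2020, 1, 18), date(2020, 1, 10)),
            anchors=(date(2020, 1, 10), date(2020, 1, 11),
                     date(2020, 1, 12), date(2020, 1, 13)),
            gammas={"valence": {"intercept": 0.3}, "arousal": {"intercept": 2.3}},
            random_sd={"valence": {"intercept": 1.0}, "arousal": {"intercept": 1.0}},
            residual_sd={"valence": np.sqrt(3.0), "arousal": np.sqrt(3.0)},
        )
        pdays, _ = gen_person_days(cfg)
        fit = fit_empty_model(pdays, "valence")
        assert fit.icc == pytest.approx(0.25, abs=0.03)

    def test_zero_between_variance_gives_null_icc_and_lrt(self):
        rng = np.random.default_rng(4)
        pdays = _balanced_pdays(rng, n_users=120, n_days=6, between=0.0)
        fit = fit_empty_model(pdays, "valence")
        assert fit.icc < 0.02
        lrt = empty_model_lrt(pdays, "valence", fit)
        assert lrt.chisq < 4.0
        assert lrt.df == 1

    def test_icc_invariant_under_outcome_scaling(self):
        rng = np.random.default_rng(9)
        pdays = _balanced_pdays(rng, n_users=60, n_days=5)
        icc1 = fit_empty_model(pdays, "valence").icc
        scaled = pdays.assign(valence=pdays["valence"] * 10.0)
        icc2 = fit_empty_model(scaled, "valence").icc
        assert icc2 == pytest.approx(icc1, abs=1e-6)

    def test_variance_components_match_profile_likelihood_grid(self):
        """3-user x 3-day toy set: REML variance components must agree with
        an independent brute-force profiled-likelihood grid search."""
        y = np.array([0.2, 0.5, 0.1, 1.1, 1.4, 0.9, -0.6, -0.2, -0.4])
        pdays = pd.DataFrame(
            {
                "user_id": np.repeat(["a", "b", "c"], 3),
                "date": [date(2020, 1, 9 + d) for d in range(3)] * 3,
                "valence": y,
            }
        )
        fit = fit_empty_model(pdays, "valence")

        def reml_m2ll(s2b, s2e):
            Vi = s2e * np.eye(3) + s2b * np.ones((3, 3))
            Vi_inv = np.linalg.inv(Vi)
            beta = sum(np.ones(3) @ Vi_inv @ y[g * 3:(g + 1) * 3] for g in range(3))
            beta /= 3 * Vi_inv.sum()
            quad = sum(
                (y[g * 3:(g + 1) * 3] - beta) @ Vi_inv @ (y[g * 3:(g + 1) * 3] - beta)
                for g in range(3)
            )
            return (
                3 * np.linalg.slogdet(Vi)[1]
                + np.log(3 * Vi_inv.sum())
                + quad
                + 8 * np.log(2 * np.pi)
            )

        lo_b, hi_b, lo_e, hi_e = 1e-6, 5.0, 1e-6, 5.0
        for _ in range(8):
            bs = np.linspace(lo_b, hi_b, 41)
            es = np.linspace(lo_e, hi_e, 41)
            vals = np.array([[reml_m2ll(b, e) for e in es] for b in bs])
            i, j = np.unravel_index(vals.argmin(), vals.shape)
            db, de = bs[1] - bs[0], es[1] - es[0]
            lo_b, hi_b = max(1e-8, bs[i] - db), bs[i] + db
            lo_e, hi_e = max(1e-8, es[j] - de), es[j] + de
        assert float(fit.cov_re.iloc[0, 0]) == pytest.approx(bs[i], abs=1e-3)
        assert fit.residual_sd**2 == pytest.approx(es[j], abs=1e-3)
        assert fit.minus2ll == pytest.approx(vals[i, j], abs=1e-3)


def _noiseless_config(seed=21, n_wuhan=30, n_non_hubei=90):
    eps = 1e-6
    return SynthConfig(
        seed=seed, n_wuhan=n_wuhan, n_non_hubei=n_non_hubei,
        p_post_day=1.0,
        random_sd={"valence": {"intercept": eps, "slope2": eps, "slope3": eps},
                   "arousal": {"intercept": eps, "slope2": eps, "slope3": eps}},
        residual_sd={"valence": 1e-4, "arousal": 1e-4},
    )


class TestPiecewiseModels:
    def test_noiseless_gamma_recovery(self):
        pdays, _ = gen_person_days(_noiseless_config())
        design = build_slope_design(FIT_WINDOW)
        fit = fit_model(pdays, "valence", "model1", design=design)
        truth = {
            "intercept": 0.337, "slope1": 0.123, "slope2": 0.118,
            "slope3": -0.146, "slope4": 0.000, "location": -0.037,
            "slope2:location": -0.172, "slope3:location": 0.109,
        }
        est = dict(zip(fit.fixed["term"], fit.fixed["estimate"]))
        for term, value in truth.items():
            assert est[term] == pytest.approx(value, abs=1e-4), term

    def test_group_difference_in_event_day_jump_equals_interaction(self):
        """By construction of the indicator coding, the locked-down vs
        comparison difference in the (Jan 22 -> Jan 23) mean change equals
        the slope2 x location coefficient exactly."""
        pdays, _ = gen_person_days(_noiseless_config(seed=22))
        d22, d23 = date(2020, 1, 22), date(2020, 1, 23)
        mean = pdays.groupby(["location", "date"])["valence"].mean()
        jump = {loc: mean[(loc, d23)] - mean[(loc, d22)] for loc in (0, 1)}
        assert jump[1] - jump[0] == pytest.approx(-0.172, abs=1e-4)

    def test_lrt_df_accounting_and_m2ll_nesting(self):
        cfg = SynthConfig(seed=31, n_wuhan=20, n_non_hubei=60, p_post_day=0.7)
        pdays, _ = gen_person_days(cfg)
        design = build_slope_design(FIT_WINDOW)
        full1 = fit_model(pdays, "valence", "model1", design=design)
        red1 = fit_model(pdays, "valence", "model1", design=design,
                         random_terms=("intercept", "slope3"))
        res1 = lrt_random_effect(full1, red1)
        assert res1.df == 3  # 1 variance + 2 covariances dropped
        assert red1.minus2ll >= full1.minus2ll - 0.01
        assert res1.chisq >= 0

        cfg2 = SynthConfig(seed=32, n_wuhan=20, n_non_hubei=60, p_post_day=0.7,
                           model="model2")
        pdays2, _ = gen_person_days(cfg2)
        full2 = fit_model(pdays2, "valence", "model2", design=design)
        red2 = fit_model(pdays2, "valence", "model2", design=design,
                         random_terms=("intercept",))
        res2 = lrt_random_effect(full2, red2)
        assert res2.df == 2  # 1 variance + 1 covariance dropped

        same = lrt_random_effect(full1, full1)
        assert same.chisq == 0.0
        assert same.p == 1.0

    def test_non_nested_random_structures_rejected(self):
        cfg = SynthConfig(seed=31, n_wuhan=20, n_non_hubei=60, p_post_day=0.7)
        pdays, _ = gen_person_days(cfg)
        design = build_slope_design(FIT_WINDOW)
        full = fit_model(pdays, "valence", "model1", design=design,
                         random_terms=("intercept", "slope2"))
        other = fit_model(pdays, "valence", "model1", design=design,
                          random_terms=("intercept", "slope3"))
        with pytest.raises(ModelError, match="nest"):
            lrt_random_effect(full, other)

    def test_model_table_has_expected_rows(self):
        cfg = SynthConfig(seed=33, n_wuhan=20, n_non_hubei=60, p_post_day=0.7)
        pdays, _ = gen_person_days(cfg)
        design = build_slope_design(FIT_WINDOW)
        fit1 = fit_model(pdays, "valence", "model1", design=design)
        assert list(fit1.fixed["term"]) == [
            "intercept", "slope1", "slope2", "slope3", "slope4",
            "location", "slope2:location", "slope3:location",
        ]
        fit2 = fit_model(pdays, "arousal", "model2", design=design)
        assert list(fit2.fixed["term"]) == [
            "intercept", "slope1", "slope2", "slope3", "slope4",
            "location", "slope4:location",
        ]
        assert tuple(fit2.random_terms) == ("intercept", "slope4")

    def test_min_users_per_day_filter(self):
        pdays = pd.DataFrame(
            {
                "user_id": ["a", "b", "c", "a"],
                "date": [date(2020, 1, 20)] * 3 + [date(2020, 1, 21)],
                "valence": [0.1, 0.2, 0.3, 0.4],
            }
        )
        out = filter_min_users_per_day(pdays, 2)
        assert set(out["date"]) == {date(2020, 1, 20)}

    def test_attach_design_drops_dates_outside_fit_window(self):
        pdays = pd.DataFrame(
            {
                "user_id": ["a", "a"],
                "date": [date(2020, 1, 10), date(2020, 1, 25)],
                "valence": [0.1, 0.2],
            }
        )
        merged = attach_design(pdays, build_slope_design(FIT_WINDOW))
        assert list(merged["date"]) == [date(2020, 1, 25)]
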