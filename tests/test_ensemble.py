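"""Model-pool enumeration, out-of-sample scoring, rank-exponential
weighting, draw generation, and the negative-binomial rare-cause family."""

import numpy as np
import pandas as pd
import pytest

from codkit.ensemble import (
    FittedModel,
    ModelSpec,
    PVScore,
    ensemble_predict_log_rate,
    ensemble_weights,
    enumerate_models,
    fit_model,
    fit_negative_binomial,
    holdout_pv,
    make_folds,
    partition_by_quality,
    predict_draws,
    predict_log_rate,
)


def _synthetic_panel(n_loc=20, n_years=10, b0=-6.0, b1=-2.0, cell_sd=0.0,
                     pop=1e6, poisson=False, seed=0, noise_cov=True):
    """Location-year panel whose truth is log rate = b0 + b1 * x1."""
    rng = np.random.default_rng(seed)
    rows = []
    for loc in range(n_loc):
        x1_base = rng.uniform(0, 1)
        for t in range(n_years):
            x1 = np.clip(x1_base + 0.02 * t, 0, 1)
            rows.append({"location": loc, "year": 2000 + t, "x1": x1})
    df = pd.DataFrame(rows)
    if noise_cov:
        df["x2"] = rng.normal(size=len(df))
    log_rate = b0 + b1 * df["x1"].to_numpy()
    if cell_sd > 0:
        log_rate = log_rate + rng.normal(0, cell_sd, len(df))
    df["true_rate"] = np.exp(log_rate)
    df["population"] = pop
    expected = df["true_rate"] * pop
    df["deaths"] = rng.poisson(expected) if poisson else expected
    df["envelope"] = df["deaths"] * 5.0 + 1.0  # all-cause stand-in
    return df


class TestEnumerate:
    def test_two_covariates_give_six_specs(self):
        pool = enumerate_models(["x1", "x2"])
        assert len(pool) == 6  # (2^2 - 1) subsets x 2 response spaces
        assert len({s.model_id for s in pool}) == 6

    def test_single_covariate_gives_two(self):
        assert len(enumerate_models(["x1"])) == 2

    def test_cap_is_deterministic(self):
        a = enumerate_models(["x1", "x2"], max_models=4)
        b = enumerate_models(["x2", "x1"], max_models=4)
        assert [s.model_id for s in a] == [s.model_id for s in b]
        assert len(a) == 4

    def test_empty_covariates_rejected(self):
        with pytest.raises(ValueError):
            enumerate_models([])


class TestHoldout:
    def test_truth_model_is_exact_on_noiseless_data(self):
        data = _synthetic_panel(n_loc=10, n_years=5)
        pool = [ModelSpec(("x1",), "log_rate")]
        scores, dropped = holdout_pv(pool, data, n_folds=3, seed=1)
        assert not dropped
        assert scores[0].rmse_level < 1e-6
        assert scores[0].rmse_trend < 1e-6

    def test_noise_covariate_scores_worse(self):
        data = _synthetic_panel(n_loc=20, n_years=8, cell_sd=0.2, seed=4)
        pool = [ModelSpec(("x1",), "log_rate"), ModelSpec(("x2",), "log_rate")]
        scores, _ = holdout_pv(pool, data, n_folds=4, seed=2)
        by_id = {s.model_id: s for s in scores}
        assert (by_id["log_rate:x2:fe"].rmse_level
                >= by_id["log_rate:x1:fe"].rmse_level)

    def test_scoring_is_deterministic(self):
        data = _synthetic_panel(n_loc=10, n_years=6, cell_sd=0.3, seed=7)
        pool = enumerate_models(["x1", "x2"])
        s1, _ = holdout_pv(pool, data, n_folds=3, seed=5)
        s2, _ = holdout_pv(pool, data, n_folds=3, seed=5)
        assert [(s.model_id, s.rmse_level, s.rmse_trend) for s in s1] == \
               [(s.model_id, s.rmse_level, s.rmse_trend) for s in s2]

    def test_wrong_sign_models_dropped_and_logged(self):
        data = _synthetic_panel(n_loc=15, n_years=6, cell_sd=0.1, seed=3)
        pool = [ModelSpec(("x1",), "log_rate")]
        # truth slope is negative; demanding positive must drop the model
        with pytest.raises(RuntimeError, match="screen"):
            holdout_pv(pool, data, n_folds=3, seed=1,
                       expected_signs={"x1": +1})

    def test_screen_keeps_correct_sign(self):
        data = _synthetic_panel(n_loc=15, n_years=6, cell_sd=0.1, seed=3)
        pool = [ModelSpec(("x1",), "log_rate"), ModelSpec(("x2",), "log_rate")]
        scores, dropped = holdout_pv(pool, data, n_folds=3, seed=1,
                                     expected_signs={"x1": -1, "x2": -1})
        assert [s.model_id for s in scores] == ["log_rate:x1:fe"]
        assert dropped and dropped[0]["model_id"] == "log_rate:x2:fe"

    def test_folds_partition_location_years(self):
        data = _synthetic_panel(n_loc=7, n_years=4)
        folds = make_folds(data, 3, seed=0)
        assert set(folds) == {0, 1, 2}
        per_ly = data.assign(fold=folds).groupby(["location", "year"])[
            "fold"].nunique()
        assert (per_ly == 1).all()


class TestWeights:
    def test_single_model_gets_weight_one(self):
        w = ensemble_weights([PVScore("m", 1.0, 1.0)])
        assert w == pytest.approx([1.0])

    def test_equal_ranks_split_evenly(self):
        scores = [PVScore("a", 1.0, 2.0), PVScore("b", 1.0, 2.0)]
        assert ensemble_weights(scores) == pytest.approx([0.5, 0.5])

    def test_rank_exponential_at_temperature_one(self):
        scores = [PVScore("a", 1.0, 1.0), PVScore("b", 2.0, 2.0),
                  PVScore("c", 3.0, 3.0)]
        w = ensemble_weights(scores, temperature=1.0)
        raw = np.exp(-np.array([1.0, 2.0, 3.0]))
        assert w == pytest.approx(raw / raw.sum())

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            ensemble_weights([PVScore("m", 1.0, 1.0)], temperature=0.0)


class TestPredictDraws:
    def test_zero_variance_single_model_collapses_to_point(self):
        data = _synthetic_panel(n_loc=5, n_years=4)
        fitted = fit_model(ModelSpec(("x1",), "log_rate"), data)
        frozen = FittedModel(fitted.spec, fitted.params,
                             np.zeros_like(fitted.cov_params), 0.0, True)
        cube = predict_draws([frozen], [1.0], data, n_draws=50, seed=0)
        point = np.exp(predict_log_rate(frozen, data)) * data["population"]
        assert np.allclose(cube.draws, point.to_numpy()[:, None])

    def test_fixed_seed_bit_identical(self):
        data = _synthetic_panel(n_loc=5, n_years=4, cell_sd=0.2, seed=2)
        fitted = fit_model(ModelSpec(("x1",), "log_rate"), data)
        a = predict_draws([fitted], [1.0], data, n_draws=30, seed=9)
        b = predict_draws([fitted], [1.0], data, n_draws=30, seed=9)
        assert (a.draws == b.draws).all()

    def test_draw_mean_tracks_point_prediction(self):
        data = _synthetic_panel(n_loc=10, n_years=5, cell_sd=0.1, seed=6)
        fitted = fit_model(ModelSpec(("x1",), "log_rate"), data)
        cube = predict_draws([fitted], [1.0], data, n_draws=1000, seed=3,
                             add_noise=False)
        point = np.exp(predict_log_rate(fitted, data)) * data["population"]
        rel = np.abs(cube.draws.mean(axis=1) - point) / point
        assert rel.max() < 0.02

    def test_nonrepresentative_rows_get_wider_draws(self):
        data = _synthetic_panel(n_loc=10, n_years=4, cell_sd=0.3, seed=8)
        data["non_representative"] = data["location"] < 5
        fitted = fit_model(ModelSpec(("x1",), "log_rate"), data)
        cube = predict_draws([fitted], [1.0], data, n_draws=400, seed=1,
                             variance_inflation=4.0)
        spread = np.log(cube.draws).std(axis=1)
        flagged = data["non_representative"].to_numpy()
        assert spread[flagged].mean() > spread[~flagged].mean()

    def test_too_few_draws_rejected(self):
        data = _synthetic_panel(n_loc=3, n_years=3)
        fitted = fit_model(ModelSpec(("x1",), "log_rate"), data)
        with pytest.raises(ValueError):
            predict_draws([fitted], [1.0], data, n_draws=1, seed=0)


class TestLogitFractionSpace:
    def test_fraction_space_round_trips_to_rates(self):
        data = _synthetic_panel(n_loc=10, n_years=5, cell_sd=0.05, seed=5)
        fitted = fit_model(ModelSpec(("x1",), "logit_fraction"), data)
        pred = predict_log_rate(fitted, data)
        obs = np.log(data["deaths"] / data["population"])
        assert np.corrcoef(pred, obs)[0, 1] > 0.95

    def test_ensemble_prediction_is_weighted_mean(self):
        data = _synthetic_panel(n_loc=6, n_years=4, cell_sd=0.1, seed=1)
        f1 = fit_model(ModelSpec(("x1",), "log_rate"), data)
        f2 = fit_model(ModelSpec(("x2",), "log_rate"), data)
        combo = ensemble_predict_log_rate([f1, f2], [0.7, 0.3], data)
        assert np.allclose(
            combo,
            0.7 * predict_log_rate(f1, data) + 0.3 * predict_log_rate(f2, data),
        )


class TestDataRichSeparation:
    def test_low_star_rows_never_in_rich_subset(self):
        data = _synthetic_panel(n_loc=10, n_years=3)
        stars = {loc: (5 if loc < 4 else 2) for loc in range(10)}
        parts = partition_by_quality(data, stars, threshold=4)
        assert set(parts["data_rich"]["location"]) == set(range(4))
        assert len(parts["data_poor"]) == len(data)

    def test_missing_star_rating_raises(self):
        data = _synthetic_panel(n_loc=3, n_years=2)
        with pytest.raises(ValueError):
            partition_by_quality(data, {0: 5}, threshold=4)


class TestNegativeBinomial:
    def test_poisson_data_gives_small_dispersion(self):
        """Counts simulated as Poisson: the NB dispersion estimate stays
        below 0.1 in at least 90 of 100 replicates."""
        rng = np.random.default_rng(0)
        hits = 0
        for i in range(100):
            y = rng.poisson(5.0, size=200)
            fit = fit_negative_binomial(y, exposure=1.0, n_draws=2, seed=i)
            hits += fit["dispersion"] < 0.1
        assert hits >= 90

    def test_constant_counts_recover_rate(self):
        fit = fit_negative_binomial(np.full(50, 4), exposure=200.0, n_draws=2)
        assert fit["rate"] == pytest.approx(4 / 200.0, rel=1e-6)

    def test_overdispersed_mean_recovery(self):
        """NB counts with mean 2, size 0.5 (NB2 alpha = 2): the fitted mean
        lands within 15% of truth in at least 90 of 100 replicates.  (The
        mean MLE is the sample mean with sampling sd ~ 0.14 at n = 500, so a
        15% band is the tightest round level a correct fit clears with
        headroom.)"""
        rng = np.random.default_rng(1)
        size, mean = 0.5, 2.0
        p = size / (size + mean)
        hits = 0
        disps = []
        for i in range(100):
            y = rng.negative_binomial(size, p, size=500)
            fit = fit_negative_binomial(y, exposure=1.0, n_draws=2, seed=i)
            hits += abs(fit["rate"] - mean) / mean < 0.15
            disps.append(fit["dispersion"])
        assert hits >= 90
        # dispersion (NB2 alpha = 1/size = 2) recovered on average
        assert abs(np.mean(disps) - 2.0) < 0.2

    def test_all_zero_series_warns_and_returns_zero_draws(self):
        with pytest.warns(UserWarning, match="all-zero"):
            fit = fit_negative_binomial(np.zeros(20, dtype=int), 100.0,
                                        n_draws=10)
        assert fit["rate"] == 0.0
        assert (fit["draws"] == 0).all()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_negative_binomial(np.array([-1, 2]), 1.0)
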