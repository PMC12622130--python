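import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import luxwear as lw
from luxwear.classifier import (
    FitConfig,
    design_matrix,
    fit_logistic,
    log_likelihood,
)
from luxwear.errors import ConfigurationError, DataError

from conftest import make_stream


def _toy_design(rng, n=20):
    """Small non-separable binary design (intercept, movement, dark)."""
    X = np.column_stack([
        np.ones(n),
        rng.integers(0, 2, n).astype(float),
        rng.integers(0, 2, n).astype(float),
    ])
    y = (rng.random(n) < expit(X @ np.array([0.3, 0.8, -0.5]))).astype(float)
    return X, y


class TestFitLogistic:
    def test_fit_dominates_surrounding_grid(self, rng):
        """The IRLS optimum beats a brute-force grid around it (oracle)."""
        X, y = _toy_design(rng)
        res = fit_logistic(X, y)
        assert res.converged
        ll_hat = log_likelihood(X, y, res.beta)
        offsets = np.linspace(-0.5, 0.5, 9)
        for d in itertools.product(offsets, repeat=3):
            assert ll_hat >= log_likelihood(X, y, res.beta + np.array(d)) - 1e-9

    def test_matches_statsmodels_mle(self, rng):
        import statsmodels.api as sm

        X, y = _toy_design(rng, n=200)
        res = fit_logistic(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(res.beta, ref.params, atol=1e-6)

    def test_row_permutation_leaves_coefficients_unchanged(self, rng):
        X, y = _toy_design(rng, n=200)
        res = fit_logistic(X, y)
        perm = rng.permutation(len(y))
        res_p = fit_logistic(X[perm], y[perm])
        np.testing.assert_allclose(res.beta, res_p.beta, atol=1e-10)

    def test_separation_is_flagged_and_still_fits(self):
        stream = make_stream(n=40, tat=[1] * 20 + [0] * 20)
        feats = lw.derive_features(stream)
        labels = np.array(["WEAR"] * 20 + ["NONWEAR"] * 20)
        with pytest.warns(UserWarning, match="separation"):
            model = lw.fit(feats, labels)
        assert model.metadata["separation"]["WEAR"] is True


class TestFitModel:
    def test_intercept_only_predicts_prevalence(self):
        # all predictors constant -> probability equals class prevalence
        stream = make_stream(n=40, start="2025-01-06 12:00")
        feats = lw.derive_features(stream.subset(np.zeros(40, bool) | True))
        feats.tod_minutes[:] = 720.0  # freeze the only varying predictor
        labels = np.array(["WEAR"] * 30 + ["NONWEAR"] * 10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = lw.fit(feats, labels)
        proba = lw.predict_proba(model, feats)
        np.testing.assert_allclose(proba["WEAR"], 0.75, atol=1e-4)
        np.testing.assert_allclose(proba["NONWEAR"], 0.25, atol=1e-4)

    def test_informative_predictor_orders_probabilities(self):
        stream = make_stream(n=40, tat=([3] * 20 + [0] * 20),
                             lux=[100] * 20 + [90] * 20)
        feats = lw.derive_features(stream)
        labels = np.array(["WEAR"] * 20 + ["NONWEAR"] * 20)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = lw.fit(feats, labels)
        proba = lw.predict_proba(model, feats)["WEAR"].to_numpy()
        assert proba[:20].min() > proba[20:].max()

    def test_unknown_rows_are_excluded(self):
        stream = make_stream(n=30, tat=[1] * 10 + [0] * 20)
        feats = lw.derive_features(stream)
        labels = np.array(["WEAR"] * 10 + ["NONWEAR"] * 10 + ["UNKNOWN"] * 10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = lw.fit(feats, labels)
        assert model.metadata["n_train"] == 20

    def test_single_class_is_error(self):
        stream = make_stream(n=10)
        feats = lw.derive_features(stream)
        with pytest.raises(DataError, match="2 outcome classes"):
            lw.fit(feats, np.array(["WEAR"] * 10))

    def test_refit_is_bit_identical(self, tester_labeled):
        feats = lw.derive_features(tester_labeled.stream)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = lw.fit(feats, tester_labeled.labels)
            b = lw.fit(feats, tester_labeled.labels)
        assert a.metadata["train_hash"] == b.metadata["train_hash"]
        for cls in a.coefficients:
            np.testing.assert_array_equal(a.coefficients[cls], b.coefficients[cls])

    def test_json_roundtrip_preserves_model(self, fitted_model):
        back = lw.WearModel.from_json(fitted_model.to_json())
        assert back.feature_names == fitted_model.feature_names
        for cls in fitted_model.coefficients:
            np.testing.assert_array_equal(
                back.coefficients[cls], fitted_model.coefficients[cls]
            )
        assert back.thresholds == fitted_model.thresholds


class TestPredict:
    def _flat_model(self, thresholds=None):
        names = ("intercept", "movement", "upright", "face_down", "dark",
                 "tod_minutes")
        return lw.WearModel(
            feature_names=names,
            coefficients={c: np.zeros(6) for c in
                          ("WEAR", "NONWEAR", "NIGHT_OK")},
            thresholds=thresholds or
            {"WEAR": 0.5, "NONWEAR": 0.5, "NIGHT_OK": 0.5},
        )

    def test_zero_coefficients_give_half_probability(self):
        feats = lw.derive_features(make_stream(n=5))
        proba = lw.predict_proba(self._flat_model(), feats)
        assert (proba.to_numpy() == 0.5).all()

    def test_large_coefficient_saturates(self):
        model = self._flat_model()
        model.coefficients["WEAR"] = np.array([0.0, 50.0, 0, 0, 0, 0])
        feats = lw.derive_features(make_stream(n=3, tat=[5, 5, 5]))
        proba = lw.predict_proba(model, feats)["WEAR"]
        assert (proba > 1 - 1e-12).all()

    def test_probability_monotone_in_predictor_with_coefficient_sign(self):
        model = self._flat_model()
        model.coefficients["WEAR"] = np.array([0.0, 2.0, 0, 0, -1.5, 0])
        moving = lw.derive_features(make_stream(n=1, tat=[1]))
        still = lw.derive_features(make_stream(n=1, tat=[0]))
        dark = lw.derive_features(make_stream(n=1, lux=[0.5]))
        lit = lw.derive_features(make_stream(n=1, lux=[100]))
        p = lambda f: lw.predict_proba(model, f)["WEAR"].iloc[0]  # noqa: E731
        assert p(moving) > p(still)
        assert p(dark) < p(lit)

    def test_exact_tie_resolves_by_priority(self):
        feats = lw.derive_features(make_stream(n=4))
        assert (lw.classify(self._flat_model(), feats) == "NIGHT_OK").all()

    def test_argmax_of_shifted_probabilities(self):
        model = self._flat_model()
        model.coefficients["WEAR"] = np.array([3.0, 0, 0, 0, 0, 0])
        assert (lw.classify(model, lw.derive_features(make_stream(n=2)))
                == "WEAR").all()

    def test_feature_arity_mismatch_is_error(self, fitted_model):
        broken = lw.WearModel(
            feature_names=("intercept", "movement"),
            coefficients={c: np.zeros(2) for c in fitted_model.coefficients},
            thresholds=dict(fitted_model.thresholds),
        )
        with pytest.raises(ConfigurationError, match="arity"):
            lw.predict_proba(broken, lw.derive_features(make_stream(n=2)))

    def test_separable_three_class_fixture_is_fully_recovered(self, rng):
        """Constructed linearly separable signatures -> 100% classification."""
        n = 120
        cls = np.repeat(["WEAR", "NONWEAR", "NIGHT_OK"], n // 3)
        tat = np.where(cls == "NONWEAR", 2, 0)
        orientation = np.where(cls == "WEAR", 2, 16)
        lux = np.where(cls == "WEAR", 500.0, 0.5)
        stream = make_stream(n=n, tat=tat, orientation=orientation, lux=lux)
        feats = lw.derive_features(stream)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = lw.fit(feats, cls)
        assert (lw.classify(model, feats) == cls).all()


class TestSplit:
    def _labeled_days(self, n_days):
        stream = make_stream(n=n_days * 1440)
        labels = np.array(["WEAR"] * len(stream))
        return lw.LabeledStream(stream, labels)

    def test_ten_days_at_eighty_percent(self):
        data = self._labeled_days(10)
        train, val = lw.split_train_validate(data, lw.SplitPlan(0.8, seed=1))
        assert len(train) == 8 * 1440
        assert len(val) == 2 * 1440

    def test_partition_is_disjoint_by_whole_days(self):
        data = self._labeled_days(5)
        train, val = lw.split_train_validate(data, lw.SplitPlan(0.6, seed=0))
        train_days = set(train.timestamps.normalize())
        val_days = set(val.timestamps.normalize())
        assert not train_days & val_days
        assert len(train) + len(val) == len(data)

    def test_same_seed_reproduces_partition(self):
        data = self._labeled_days(6)
        a = lw.split_train_validate(data, lw.SplitPlan(0.8, seed=9))
        b = lw.split_train_validate(data, lw.SplitPlan(0.8, seed=9))
        assert (a[0].timestamps == b[0].timestamps).all()

    def test_single_day_is_error(self):
        with pytest.raises(DataError, match="2 day blocks"):
            lw.split_train_validate(self._labeled_days(1), lw.SplitPlan(0.8, 0))

    def test_bad_fraction_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            lw.SplitPlan(train_fraction=1.2)
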