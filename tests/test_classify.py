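import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from mirnafeat.classify import (
    PUBLISHED_FEATURES,
    PerfectSeparationError,
    cross_validate,
    predict,
    published_model,
    roc_area,
    train_logistic,
    zero_r,
)

from conftest import make_table


def simulate_from_model(model, n, rng):
    """Labelled table whose class probabilities follow ``model`` on
    hairpin-scale feature distributions."""
    cols = {
        "n_helix": rng.poisson(4.0, size=n).astype(float),
        "n_stack": rng.normal(35.0, 12.0, size=n),
        "length": rng.normal(110.0, 40.0, size=n),
        "MFE": rng.normal(-50.0, 20.0, size=n),
    }
    logit = model.intercept + sum(
        beta * cols[name] for name, beta in model.coefficients.items()
    )
    p = 1.0 / (1.0 + np.exp(-logit))
    labels = np.where(rng.random(n) < p, "animal", "plant")
    return make_table(cols, labels, rng=rng)


class TestPublishedModel:
    def test_printed_parameters(self):
        m = published_model()
        assert m.intercept == 6.1436
        assert m.coefficients == {
            "n_helix": 0.0893,
            "n_stack": -0.0691,
            "length": -0.0241,
            "MFE": 0.0263,
        }
        assert len(m.coefficients) == 4
        assert m.positive_label == "animal"

    def test_logit_at_origin_is_intercept(self):
        m = published_model()
        origin = {name: 0.0 for name in PUBLISHED_FEATURES}
        assert m.linear_predictor(origin) == 6.1436
        assert m.predict_proba(origin) == pytest.approx(0.99786, abs=5e-6)

    @pytest.mark.parametrize(
        "fv, logit, proba, call",
        [
            ({"n_helix": 8, "n_stack": 45, "length": 200, "MFE": -90}, -3.4385, 0.0312, "plant"),
            ({"n_helix": 3, "n_stack": 20, "length": 85, "MFE": -35}, 2.0605, 0.887, "animal"),
        ],
    )
    def test_worked_examples(self, fv, logit, proba, call):
        m = published_model()
        assert m.linear_predictor(fv) == pytest.approx(logit, abs=1e-10)
        assert predict(m, fv) == pytest.approx(proba, abs=5e-4)
        assert m.predict_label(fv) == call

    def test_missing_feature_named_in_error(self):
        m = published_model()
        with pytest.raises(KeyError, match="MFE"):
            m.predict_proba({"n_helix": 1, "n_stack": 2, "length": 3})

    def test_monotone_in_each_coefficient_sign(self):
        m = published_model()
        base = {"n_helix": 4.0, "n_stack": 30.0, "length": 100.0, "MFE": -40.0}
        p0 = m.predict_proba(base)
        for name, beta in m.coefficients.items():
            bumped = dict(base)
            bumped[name] += 10.0
            p1 = m.predict_proba(bumped)
            assert (p1 > p0) == (beta > 0)


class TestTrainLogistic:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(131)
        n = 1000
        labels = ["animal"] * 700 + ["plant"] * 300
        table = make_table({}, labels, rng=rng)
        # constant pseudo-feature forces an (almost) intercept-only fit
        table.values["n_bulge"] = 0.0
        fit = train_logistic(table, ["n_bulge"], positive_label="animal", ridge=1e-12)
        assert fit.model.intercept == pytest.approx(math.log(0.7 / 0.3), abs=1e-6)

    def test_parameter_recovery_within_3_se(self):
        rng = np.random.default_rng(137)
        truth = published_model()
        table = simulate_from_model(truth, 5000, rng)
        fit = train_logistic(table, list(PUBLISHED_FEATURES), positive_label="animal")
        assert fit.converged
        est = [fit.model.intercept, *fit.model.coefficients.values()]
        true = [truth.intercept, *truth.coefficients.values()]
        for e, t, se in zip(est, true, fit.standard_errors):
            assert abs(e - t) < 3 * se

    def test_matches_independent_glm_fit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(139)
        table = simulate_from_model(published_model(), 2000, rng)
        fit = train_logistic(table, list(PUBLISHED_FEATURES), positive_label="animal")
        X = sm.add_constant(table.values[list(PUBLISHED_FEATURES)].to_numpy())
        y = (table.labels == "animal").to_numpy(dtype=float)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        est = np.array([fit.model.intercept, *fit.model.coefficients.values()])
        assert np.allclose(est, ref.params, atol=1e-6)
        assert np.allclose(fit.standard_errors, ref.bse, rtol=1e-4)

    def test_null_slopes_near_zero(self):
        rng = np.random.default_rng(149)
        n = 2000
        labels = np.where(rng.random(n) < 0.5, "animal", "plant")
        table = make_table({}, labels, rng=rng)
        fit = train_logistic(table, ["length", "MFE"], positive_label="animal")
        for beta, se in zip(fit.model.coefficients.values(), fit.standard_errors[1:]):
            assert abs(beta) < 3 * se

    def test_perfect_separation_raises_and_ridge_rescues(self):
        rng = np.random.default_rng(151)
        n = 200
        x = np.concatenate([rng.normal(-5, 1, n // 2), rng.normal(5, 1, n // 2)])
        labels = ["plant"] * (n // 2) + ["animal"] * (n // 2)
        table = make_table({"length": x}, labels, rng=rng)
        with pytest.raises(PerfectSeparationError):
            train_logistic(table, ["length"], positive_label="animal")
        fit = train_logistic(table, ["length"], positive_label="animal", ridge=1e-6)
        assert np.isfinite(fit.model.coefficients["length"])


class TestZeroR:
    def test_majority_fraction(self):
        rng = np.random.default_rng(157)
        labels = ["animal"] * 70 + ["plant"] * 30
        table = make_table({}, labels, rng=rng)
        m = zero_r(table)
        assert m.majority_label == "animal"
        assert m.majority_fraction == pytest.approx(0.7)

    def test_tie_breaks_lexicographically(self):
        rng = np.random.default_rng(163)
        table = make_table({}, ["plant", "animal"] * 10, rng=rng)
        assert zero_r(table).majority_label == "animal"

    def test_cv_baseline_metrics(self):
        rng = np.random.default_rng(167)
        labels = ["animal"] * 70 + ["plant"] * 30
        table = make_table({}, labels, rng=rng)
        rep = cross_validate(table, ["length"], model_spec="zero_r", k=5, seed=0)
        assert rep.roc_area == pytest.approx(0.5)
        assert rep.tp_rate == pytest.approx(0.7)


class TestRocArea:
    def test_rank_auc_matches_trapezoidal_integration(self):
        rng = np.random.default_rng(173)
        for _ in range(50):
            n = int(rng.integers(10, 200))
            y = rng.random(n) < 0.4
            if y.all() or not y.any():
                continue
            scores = np.round(rng.normal(size=n), 1)  # ties included
            assert roc_area(y, scores) == pytest.approx(
                roc_auc_score(y, scores), abs=1e-10
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_area(np.array([True, True]), np.array([0.1, 0.2]))


class TestCrossValidate:
    def test_separable_data_is_perfect(self):
        rng = np.random.default_rng(179)
        n = 300
        x = np.concatenate([rng.normal(-8, 1, n // 2), rng.normal(8, 1, n // 2)])
        labels = ["plant"] * (n // 2) + ["animal"] * (n // 2)
        table = make_table({"length": x}, labels, rng=rng)
        rep = cross_validate(table, ["length"], k=10, seed=3)
        assert rep.precision == pytest.approx(1.0)
        assert rep.roc_area == pytest.approx(1.0)

    def test_shuffled_labels_are_chance(self):
        rng = np.random.default_rng(181)
        n = 1000
        labels = np.where(rng.random(n) < 0.5, "animal", "plant")
        table = make_table({}, labels, rng=rng)
        rep = cross_validate(table, ["length", "MFE"], k=10, seed=4)
        assert abs(rep.roc_area - 0.5) < 0.05

    def test_confusion_counts_sum_to_n(self):
        rng = np.random.default_rng(191)
        table = simulate_from_model(published_model(), 300, rng)
        rep = cross_validate(table, list(PUBLISHED_FEATURES), k=5, seed=5)
        total = sum(sum(row.values()) for row in rep.confusion.values())
        assert total == rep.n == 300

    def test_class_smaller_than_k_rejected(self):
        rng = np.random.default_rng(193)
        labels = ["animal"] * 5 + ["plant"] * 50
        table = make_table({}, labels, rng=rng)
        with pytest.raises(ValueError):
            cross_validate(table, ["length"], k=10, seed=0)
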