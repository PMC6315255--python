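import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from funcprofile.ordinal import OrdinalGAM, class_weights


def proportional_odds_sample(rng, n=300, slope=1.5, thresholds=(-1.0, 1.0)):
    x = rng.normal(0, 1, n)
    latent = slope * x + rng.logistic(0, 1, n)
    y = np.where(latent < thresholds[0], 1, np.where(latent < thresholds[1], 2, 3))
    return pd.DataFrame({"x": x}), y


class TestClassWeights:
    @pytest.mark.parametrize(
        "cats,expected",
        [
            ([1, 2, 2, 3], [4 / 3, 2 / 3, 2 / 3, 4 / 3]),
            ([1, 2, 3], [1.0, 1.0, 1.0]),
        ],
    )
    def test_inverse_prevalence(self, cats, expected):
        np.testing.assert_allclose(class_weights(cats), expected)

    def test_quartile_design_pattern(self):
        # 1:2:1 design: outer quartile classes get 4/3, the middle 2/3
        cats = [1] * 10 + [2] * 20 + [3] * 10
        w = class_weights(cats)
        assert w[0] == pytest.approx(4 / 3)
        assert w[15] == pytest.approx(2 / 3)
        assert np.mean(w) == pytest.approx(1.0)

    def test_absent_category_ignored(self):
        w = class_weights([1, 1, 3, 3])
        np.testing.assert_allclose(w, [1, 1, 1, 1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            class_weights([])


class TestLinearReduction:
    def test_matches_proportional_odds_mle(self):
        """Linear smooths + no penalty == unpenalized cumulative logit."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        rng = np.random.default_rng(12)
        n = 200
        X = pd.DataFrame({"x1": rng.normal(0, 1, n), "x2": rng.uniform(-2, 2, n)})
        eta = 1.2 * X["x1"] - 0.7 * X["x2"]
        y = np.asarray(
            np.digitize(eta + rng.logistic(0, 1, n), [-1.0, 1.0]) + 1
        )
        ours = OrdinalGAM(smooth="linear", penalized=False).fit(X, y)
        ref = OrderedModel(y, X.to_numpy(), distr="logit").fit(
            method="bfgs", disp=False
        )
        coefs = ours.linear_coefficients()
        assert abs(coefs["x1"] - ref.params[0]) < 1e-3
        assert abs(coefs["x2"] - ref.params[1]) < 1e-3

    def test_weight_duplication_invariance(self):
        rng = np.random.default_rng(3)
        X, y = proportional_odds_sample(rng, n=150)
        base = OrdinalGAM(smooth="linear", penalized=False).fit(X, y)
        dup2 = y == 2
        X2 = pd.concat([X, X[dup2]], ignore_index=True)
        y2 = np.r_[y, y[dup2]]
        w2 = np.ones(len(y2))
        w2[np.flatnonzero(dup2)] = 0.5
        w2[len(y):] = 0.5
        dup = OrdinalGAM(smooth="linear", penalized=False).fit(X2, y2, weights=w2)
        assert abs(
            base.linear_coefficients()["x"] - dup.linear_coefficients()["x"]
        ) < 1e-5


@pytest.fixture(scope="module")
def fit():
    rng = np.random.default_rng(5)
    X, y = proportional_odds_sample(rng, n=400)
    return OrdinalGAM().fit(X, y)


class TestPrediction:
    def test_latent_between_thresholds_gives_middle_category(self, fit):
        th = fit.thresholds_
        # find x with latent midway between the thresholds
        grid = pd.DataFrame({"x": np.linspace(-4, 4, 400)})
        eta = fit.latent(grid)
        mid = grid.iloc[[int(np.argmin(np.abs(eta - th.mean())))]]
        assert fit.predict(mid)[0] == 2

    def test_extreme_latent_gives_extreme_category(self, fit):
        proba = fit.predict_proba(pd.DataFrame({"x": [-50.0, 50.0]}))
        # clipped to the training range, but direction must hold
        assert fit.predict(pd.DataFrame({"x": [-50.0]}))[0] in (1, 3)

    def test_probability_simplex(self, fit):
        rng = np.random.default_rng(0)
        proba = fit.predict_proba(pd.DataFrame({"x": rng.normal(0, 2, 200)}))
        assert (proba >= 0).all()
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)

    def test_cumulative_probability_monotone_in_latent(self, fit):
        X = pd.DataFrame({"x": np.linspace(-3, 3, 50)})
        eta = fit.latent(X)
        order = np.argsort(eta)
        proba = fit.predict_proba(X)
        cum1 = proba[:, 0][order]
        cum2 = (proba[:, 0] + proba[:, 1])[order]
        assert (np.diff(cum1) <= 1e-12).all()
        assert (np.diff(cum2) <= 1e-12).all()

    def test_missing_predictor_rejected(self, fit):
        with pytest.raises(ValueError, match="missing"):
            fit.predict(pd.DataFrame({"z": [1.0]}))

    def test_single_category_rejected(self):
        with pytest.raises(ValueError):
            OrdinalGAM().fit(pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]}), [2, 2, 2, 2])


def test_threshold_probability_arithmetic():
    """p1, p2, p3 follow the cumulative-logit identities."""
    theta = np.array([-1.0, 1.0])
    for eta in (-3.0, 0.0, 2.5):
        p1 = expit(theta[0] - eta)
        p2 = expit(theta[1] - eta) - p1
        p3 = 1 - expit(theta[1] - eta)
        assert p1 + p2 + p3 == pytest.approx(1.0)
    # eta = 0 between thresholds (-1, 1): middle category maximal
    probs = [expit(-1), expit(1) - expit(-1), 1 - expit(1)]
    assert int(np.argmax(probs)) == 1


def test_null_response_shrinks_every_smooth():
    """With the response independent of all predictors, each smooth's
    effective degrees of freedom collapse to (at most) its null space
    and the fit carries no held-in rank correlation."""
    import warnings

    from funcprofile.evaluation import goodman_kruskal_gamma

    rng = np.random.default_rng(21)
    n = 500
    X = pd.DataFrame({f"x{i}": rng.normal(0, 1, n) for i in range(4)})
    y = rng.integers(1, 4, n)
    fit = OrdinalGAM().fit(X, y)
    assert all(v <= 1.2 for v in fit.edf_.values())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        g = goodman_kruskal_gamma(fit.predict(X), y)
    # a fully shrunk fit may predict a single category (Gamma undefined)
    assert np.isnan(g) or abs(g) <= 0.15


class TestPartialEffects:
    def test_linear_truth_within_band(self):
        rng = np.random.default_rng(8)
        n = 400
        x = rng.uniform(-2, 2, n)
        y = np.digitize(1.2 * x + rng.logistic(0, 1, n), [-1, 1]) + 1
        fit = OrdinalGAM().fit(pd.DataFrame({"x": x}), y)
        pe = fit.partial_effect("x")
        true_centered = 1.2 * pe.points - np.mean(1.2 * x)
        cover = np.abs(pe.effect - true_centered) <= 2.5 * np.maximum(pe.se, 1e-6)
        assert cover.mean() >= 0.9

    def test_flat_truth_band_covers_zero(self):
        rng = np.random.default_rng(9)
        n = 400
        x = rng.uniform(-2, 2, n)
        y = rng.integers(1, 4, n)
        fit = OrdinalGAM().fit(pd.DataFrame({"x": x}), y)
        pe = fit.partial_effect("x")
        covers = np.abs(pe.effect) <= 2 * pe.se + 1e-9
        assert covers.mean() >= 0.9

    def test_extrapolation_flagged_and_band_widens(self):
        rng = np.random.default_rng(10)
        X, y = proportional_odds_sample(rng, n=300)
        fit = OrdinalGAM().fit(X, y)
        hi = float(X["x"].max())
        pts = np.array([hi, hi + 1.0, hi + 2.0, hi + 3.0])
        pe = fit.partial_effect("x", points=pts)
        assert list(pe.extrapolated) == [False, True, True, True]
        assert (np.diff(pe.se[1:]) > 0).all()

    def test_unknown_predictor_rejected(self):
        rng = np.random.default_rng(1)
        X, y = proportional_odds_sample(rng, n=200)
        fit = OrdinalGAM().fit(X, y)
        with pytest.raises(ValueError):
            fit.partial_effect("nope")
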