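import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from coralhsm.maxent_sdm import (
    FeatureSpec,
    MaxentModel,
    build_features,
    default_betas,
    enabled_classes,
    featurize,
    fit_maxent,
    jackknife_importance,
    logistic_output,
    training_gain,
)


def _binary_problem(n_bg=1000, bg_frac=0.5, pres_frac=0.8, m=100):
    """Single raw binary feature; background split bg_frac, presences
    pres_frac."""
    B = np.zeros((n_bg, 1))
    B[: int(round(bg_frac * n_bg)), 0] = 1.0
    P = np.zeros((m, 1))
    P[: int(round(pres_frac * m)), 0] = 1.0
    return P, B


class TestFeatureClasses:
    @pytest.mark.parametrize(
        "m,expected",
        [
            (5, ("linear",)),
            (12, ("linear", "quadratic")),
            (50, ("linear", "quadratic", "hinge")),
            (203, ("linear", "quadratic", "hinge", "product")),
        ],
    )
    def test_classes_by_sample_size(self, m, expected):
        assert enabled_classes(m) == expected

    def test_build_features_m12_has_no_hinge_or_product(self):
        rng = np.random.default_rng(0)
        bg = {"a": rng.normal(size=100), "b": rng.normal(size=100)}
        specs = build_features(bg, m=12)
        assert {s.kind for s in specs} == {"linear", "quadratic"}

    def test_constant_variable_dropped_with_warning(self):
        bg = {"a": np.ones(50), "b": np.linspace(0, 1, 50)}
        with pytest.warns(UserWarning):
            specs = build_features(bg, m=20)
        assert all(s.variable == "b" for s in specs)

    def test_scaled_features_in_unit_interval(self):
        rng = np.random.default_rng(1)
        bg = {"a": rng.normal(size=200), "b": rng.exponential(size=200)}
        specs = build_features(bg, m=100)
        F = featurize(specs, bg)
        assert F.min() >= 0.0 and F.max() <= 1.0

    def test_clamping_outside_background_range(self):
        bg = {"a": np.linspace(0, 1, 50)}
        specs = build_features(bg, m=5)
        F = featurize(specs, {"a": np.array([-10.0, 10.0])})
        assert F[0, 0] == 0.0 and F[1, 0] == 1.0

    def test_too_few_presences_raises(self):
        with pytest.raises(ValueError):
            build_features({"a": np.arange(10.0)}, m=1)


class TestFit:
    def test_no_signal_gives_null_model(self):
        rng = np.random.default_rng(0)
        B = rng.uniform(size=(500, 2))
        P = B.copy()  # presence empirical distribution == background
        model = fit_maxent(P, B, betas=np.array([0.05, 0.05]))
        np.testing.assert_allclose(model.lam, 0.0, atol=1e-6)
        assert model.gain == pytest.approx(0.0, abs=1e-8)

    def test_binary_feature_closed_form(self):
        """bg fraction 0.5, presence fraction 0.8, beta=0 -> lambda = ln 4,
        cross-checked against a 1-D numeric solve of the moment condition."""
        P, B = _binary_problem()
        model = fit_maxent(P, B, betas=np.zeros(1), convergence=1e-12, max_iterations=2000)
        numeric = brentq(lambda lam: 0.5 * np.exp(lam) / (0.5 * np.exp(lam) + 0.5) - 0.8, -10, 10)
        assert model.lam[0] == pytest.approx(np.log(4.0), abs=1e-3)
        assert model.lam[0] == pytest.approx(numeric, abs=1e-3)

    def test_regularized_moment_gap_equals_beta(self):
        """With beta=0.05 the active feature's moment gap sits exactly on the
        constraint boundary; verified against a grid-search minimiser."""
        P, B = _binary_problem()
        beta = 0.05
        model = fit_maxent(P, B, betas=np.array([beta]), convergence=1e-12, max_iterations=2000)
        q = np.exp(B @ model.lam - model.log_z)
        gap = abs(q @ B[:, 0] - P[:, 0].mean())
        assert gap == pytest.approx(beta, abs=1e-4)

        # independent oracle: dense grid search over lambda
        lams = np.linspace(0, 3, 30001)
        fbar = P[:, 0].mean()
        log_z = np.array([np.log(0.5 * np.exp(l) + 0.5) + np.log(len(B)) for l in lams])
        obj = log_z - lams * fbar + beta * np.abs(lams)
        assert model.lam[0] == pytest.approx(lams[np.argmin(obj)], abs=2e-3)

    def test_kkt_moment_condition_random_problems(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n_bg, m = 400, 60
            j = rng.integers(1, 3)
            B = rng.uniform(size=(n_bg, j))
            idx = rng.choice(n_bg, size=m, replace=False, p=None)
            w = np.exp(2 * B[:, 0])
            idx = rng.choice(n_bg, size=m, replace=True, p=w / w.sum())
            P = B[idx]
            betas = rng.uniform(0.01, 0.1, size=j)
            model = fit_maxent(P, B, betas=betas, convergence=1e-10, max_iterations=1000)
            q = np.exp(B @ model.lam - model.log_z)
            gaps = np.abs(q @ B - P.mean(axis=0))
            assert (gaps <= betas + 1e-4).all()

    def test_objective_monotone_nonincreasing(self):
        P, B = _binary_problem()
        model = fit_maxent(P, B, betas=np.array([0.01]))
        diffs = np.diff(model.objective_history)
        assert (diffs <= 1e-12).all()

    def test_normalization(self):
        rng = np.random.default_rng(7)
        B = rng.uniform(size=(300, 2))
        P = B[rng.choice(300, 40)]
        model = fit_maxent(P, B, betas=np.array([0.02, 0.02]))
        q = np.exp(B @ model.lam - model.log_z)
        assert q.sum() == pytest.approx(1.0, abs=1e-10)

    def test_nonfinite_raises(self):
        P = np.array([[np.nan], [1.0]])
        B = np.ones((10, 1))
        with pytest.raises(ValueError):
            fit_maxent(P, B, betas=np.zeros(1))

    def test_needs_two_presences(self):
        with pytest.raises(ValueError):
            fit_maxent(np.ones((1, 1)), np.ones((5, 1)), betas=np.zeros(1))


class TestLogisticOutput:
    def _null_model(self, n_bg=100):
        return MaxentModel(
            features=[], lam=np.zeros(1), beta=np.zeros(1), log_z=np.log(n_bg),
            entropy=np.log(n_bg), gain=0.0, n_background=n_bg, iterations=0,
            converged=True,
        )

    def test_null_model_is_half_everywhere(self):
        model = self._null_model()
        hsi = logistic_output(model, np.random.default_rng(0).uniform(size=(50, 1)) * 0)
        np.testing.assert_allclose(hsi, 0.5, atol=1e-12)

    def test_algebraic_identity(self):
        # e^H q = 3  ->  HSI = 0.75
        model = MaxentModel(
            features=[], lam=np.array([np.log(3.0)]), beta=np.zeros(1), log_z=0.0,
            entropy=0.0, gain=0.0, n_background=1, iterations=0, converged=True,
        )
        hsi = logistic_output(model, np.array([[1.0]]))
        assert hsi[0] == pytest.approx(0.75)

    def test_vanishing_q_gives_zero(self):
        model = MaxentModel(
            features=[], lam=np.array([1.0]), beta=np.zeros(1), log_z=0.0,
            entropy=0.0, gain=0.0, n_background=1, iterations=0, converged=True,
        )
        hsi = logistic_output(model, np.array([[-1000.0]]))  # q -> 0
        assert hsi[0] == pytest.approx(0.0, abs=1e-12)

    def test_fitted_null_matches(self):
        rng = np.random.default_rng(0)
        B = rng.uniform(size=(200, 1))
        model = fit_maxent(B.copy(), B, betas=np.array([0.1]))
        hsi = logistic_output(model, B)
        np.testing.assert_allclose(hsi, 0.5, atol=1e-5)


class TestTrainingGain:
    def test_null_gain_zero(self):
        rng = np.random.default_rng(0)
        B = rng.uniform(size=(200, 1))
        model = fit_maxent(B.copy(), B, betas=np.array([0.1]))
        assert training_gain(model, B) == pytest.approx(0.0, abs=1e-8)

    def test_binary_example_hand_evaluated(self):
        # lambda = ln 4, N_bg split 500/500: gain = 0.8 ln 1.6 + 0.2 ln 0.4
        P, B = _binary_problem()
        model = fit_maxent(P, B, betas=np.zeros(1), convergence=1e-12, max_iterations=2000)
        expected = 0.8 * np.log(1.6) + 0.2 * np.log(0.4)
        assert training_gain(model, P) == pytest.approx(expected, abs=1e-3)
        assert model.gain == pytest.approx(expected, abs=1e-3)

    def test_gain_monotone_in_regularization(self):
        P, B = _binary_problem()
        gains = [
            fit_maxent(P, B, betas=np.array([b]), convergence=1e-12, max_iterations=2000).gain
            for b in (0.2, 0.1, 0.05, 0.0)
        ]
        assert all(g2 >= g1 - 1e-9 for g1, g2 in zip(gains, gains[1:]))

    def test_gain_monotone_in_feature_set(self):
        rng = np.random.default_rng(3)
        B = rng.uniform(size=(400, 3))
        w = np.exp(1.5 * B[:, 0] - B[:, 1])
        P = B[rng.choice(400, 80, p=w / w.sum())]
        g = []
        for j in (1, 2, 3):
            model = fit_maxent(P[:, :j], B[:, :j], betas=np.zeros(j),
                               convergence=1e-10, max_iterations=2000)
            g.append(model.gain)
        assert g[0] <= g[1] + 1e-6 and g[1] <= g[2] + 1e-6


class TestDefaultBetas:
    def test_beta_formula(self):
        specs = [FeatureSpec("a", "a", "linear", 0, 1), FeatureSpec("h", "a", "hinge", 0, 1, knot=0.5)]
        P = np.column_stack([np.linspace(0, 1, 100), np.linspace(0, 1, 100)])
        betas = default_betas(specs, P, reg_multiplier=1.0)
        sd = P.std(axis=0)
        assert betas[0] == pytest.approx(0.05 * sd[0] / 10.0)  # c(100)=0.05, sqrt(100)=10
        assert betas[1] == pytest.approx(0.5 * sd[1] / 10.0)  # hinge constant 0.5

    def test_multiplier_scales(self):
        specs = [FeatureSpec("a", "a", "linear", 0, 1)]
        P = np.linspace(0, 1, 50)[:, None]
        b1 = default_betas(specs, P, 1.0)
        b2 = default_betas(specs, P, 2.0)
        assert b2[0] == pytest.approx(2 * b1[0])


@pytest.fixture(scope="module")
def temp_driven():
    """Suitability driven by temperature only; one pure-noise variable; an
    independent evaluation draw from the same presence process."""
    rng = np.random.default_rng(12)
    n = 600
    bg = pd.DataFrame({"temperature": rng.normal(size=n), "noise": rng.normal(size=n)})
    w = np.exp(2.5 * bg["temperature"].to_numpy())
    p = w / w.sum()
    pres = bg.iloc[rng.choice(n, size=120, replace=True, p=p)].reset_index(drop=True)
    test = bg.iloc[rng.choice(n, size=120, replace=True, p=p)].reset_index(drop=True)
    return pres, bg, test


class TestJackknife:
    def test_driver_dominates(self, temp_driven):
        pres, bg, _ = temp_driven
        table = jackknife_importance(pres, bg)
        full_specs = build_features(bg, len(pres))
        full = fit_maxent(
            featurize(full_specs, pres), featurize(full_specs, bg), features=full_specs
        )
        assert table.loc["temperature", "gain_with_only"] >= 0.9 * full.gain
        assert table.loc["noise", "gain_with_only"] <= 0.1 * full.gain

    def test_noise_variable_auc_near_half(self, temp_driven):
        pres, bg, test = temp_driven
        table = jackknife_importance(pres, bg, test_values=test)
        assert table.loc["noise", "auc_with_only"] == pytest.approx(0.5, abs=0.05)

    def test_single_variable_without_is_null(self):
        rng = np.random.default_rng(5)
        bg = pd.DataFrame({"only": rng.normal(size=300)})
        pres = bg.iloc[rng.choice(300, 40)].reset_index(drop=True)
        table = jackknife_importance(pres, bg)
        assert table.loc["only", "gain_without"] == pytest.approx(0.0)
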