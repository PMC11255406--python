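"""MaxEnt core: features, fitting, prediction, AICc, tuning, thresholds.

Oracle strategy: the penalized optimum is cross-checked against dense grid
search of the same objective on 1-2-feature instances; parameter recovery
uses presences drawn from a known Gibbs distribution; AICc and the
logistic transform are checked against hand arithmetic.
"""

import numpy as np
import pytest
from scipy.special import logsumexp

from bftb_sdm.maxent import (
    compute_aicc,
    compute_thresholds,
    evaluate_auc,
    expand_features,
    fit_maxent,
    predict_logistic,
    predict_raw,
)


def make_instance(n_bg=500, n_pres=500, lam_true=2.0, seed=0, d=1):
    """Background uniform in [0,1]^d; presences ~ exp(lam . f)/Z."""
    rng = np.random.default_rng(seed)
    bg = rng.uniform(0, 1, (n_bg, d))
    lam = np.full(d, lam_true)
    w = np.exp(bg @ lam)
    w /= w.sum()
    pres = bg[rng.choice(n_bg, size=n_pres, replace=True, p=w)]
    env = np.vstack([bg, pres])
    bg_rows = np.arange(n_bg)
    pr_rows = np.arange(n_bg, n_bg + n_pres)
    return env, bg_rows, pr_rows


class TestFeatures:
    def test_linear_single_variable(self):
        vals = np.array([[1.0], [3.0], [5.0]])
        fs, F = expand_features(vals, {"L"})
        assert fs.n_features == 1
        assert F[:, 0] == pytest.approx([0.0, 0.5, 1.0])

    def test_lq_two_variables_has_four_features(self):
        vals = np.random.default_rng(0).uniform(0, 1, (50, 2))
        fs, F = expand_features(vals, {"L", "Q"})
        assert fs.n_features == 4

    def test_product_features_count_pairs(self):
        vals = np.random.default_rng(0).uniform(0, 1, (50, 3))
        fs, _ = expand_features(vals, {"L", "Q", "P"})
        # 3 linear + 3 quadratic + C(3,2) = 3 products
        assert fs.n_features == 9
        assert sum(d[0] == "P" for d in fs.descriptors) == 3

    def test_all_features_in_unit_interval(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 5, (200, 2))
        fs, F = expand_features(vals, {"L", "Q", "H", "P", "T"}, knots_per_var=5)
        assert F.min() >= 0.0 and F.max() <= 1.0
        # out-of-range projection is clamped
        F2 = fs.transform(np.array([[100.0, -100.0]]))
        assert F2.min() >= 0.0 and F2.max() <= 1.0

    def test_constant_variable_dropped_with_warning(self, caplog):
        vals = np.column_stack([np.ones(20), np.linspace(0, 1, 20)])
        with caplog.at_level("WARNING"):
            fs, _ = expand_features(vals, {"L", "Q"})
        assert fs.n_features == 2  # only the varying column contributes
        assert "constant" in caplog.text

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            expand_features(np.ones((5, 1)), {"X"})


class TestFit:
    def test_raw_distribution_sums_to_one(self):
        env, bg, pr = make_instance(seed=3)
        fs, F = expand_features(env, {"L", "Q"}, background_rows=bg)
        model = fit_maxent(pr, bg, F, rm=1.0, features=fs)
        assert abs(predict_raw(model, F[bg]).sum() - 1.0) < 1e-9

    def test_presences_equal_background_zeroes_coefficients(self):
        """With presence = background the empirical means match exactly and
        the L1 penalty keeps every coefficient at zero (uniform model)."""
        rng = np.random.default_rng(4)
        bg = rng.uniform(0, 1, (300, 1))
        fs, F = expand_features(bg, {"L"})
        idx = np.arange(300)
        model = fit_maxent(idx, idx, F, rm=1.0, features=fs)
        assert np.all(np.abs(model.lambdas) < 1e-6)
        raw = predict_raw(model, F)
        assert raw == pytest.approx(np.full(300, 1 / 300), abs=1e-9)

    def test_single_feature_lambda_recovery(self):
        """Presences generated from exp(2 f)/Z: fitted coefficient lands
        within +-0.3 of the generating value at n=500, rm=0.5."""
        env, bg, pr = make_instance(n_pres=500, lam_true=2.0, seed=0)
        fs, F = expand_features(env, {"L"}, background_rows=bg)
        model = fit_maxent(pr, bg, F, rm=0.5, features=fs)
        assert model.lambdas[0] == pytest.approx(2.0, abs=0.3)

    @pytest.mark.parametrize("d,seed", [(1, 0), (1, 5), (2, 2)])
    def test_grid_search_oracle(self, d, seed):
        """Penalized optimum matches a dense grid search of the same
        objective to 1e-3."""
        env, bg, pr = make_instance(n_bg=200, n_pres=150, lam_true=1.5, seed=seed, d=d)
        fs, F = expand_features(env, {"L"}, background_rows=bg)
        model = fit_maxent(pr, bg, F, rm=1.0, features=fs)
        Fb, Fp = F[bg], F[pr]
        beta = model.beta

        def objective(lam):
            return (
                Fp.mean(axis=0) @ lam
                - logsumexp(Fb @ lam)
                - beta @ np.abs(lam)
            )

        if d == 1:
            grid = np.arange(-4, 4, 1e-3)[:, None]
        else:
            axis = np.arange(-3, 3, 0.05)
            grid = np.array(np.meshgrid(axis, axis)).reshape(2, -1).T
        vals = [objective(g) for g in grid]
        assert objective(model.lambdas) >= max(vals) - 1e-3

    def test_fit_beats_zero_vector(self):
        env, bg, pr = make_instance(seed=7)
        fs, F = expand_features(env, {"L", "Q"}, background_rows=bg)
        model = fit_maxent(pr, bg, F, rm=1.0, features=fs)
        Fb, Fp = F[bg], F[pr]

        def objective(lam):
            return Fp.mean(0) @ lam - logsumexp(Fb @ lam) - model.beta @ np.abs(lam)

        assert objective(model.lambdas) >= objective(np.zeros_like(model.lambdas))

    def test_huge_regularization_zeroes_everything(self):
        env, bg, pr = make_instance(seed=9)
        fs, F = expand_features(env, {"L", "Q"}, background_rows=bg)
        model = fit_maxent(pr, bg, F, rm=1e6, features=fs)
        assert np.all(np.abs(model.lambdas) < 1e-6)

    def test_objective_never_decreases_between_iterations(self):
        env, bg, pr = make_instance(seed=11)
        fs, F = expand_features(env, {"L", "Q"}, background_rows=bg)
        trace: list[float] = []
        fit_maxent(pr, bg, F, rm=0.5, features=fs, trace=trace)
        assert len(trace) >= 2
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-12)


class TestPredict:
    def test_hand_computed_three_cell_example(self):
        """lambda=(1.0, -0.5) over tabulated features: raw and logistic
        follow spreadsheet arithmetic."""
        from bftb_sdm.maxent import FeatureSet, MaxEntModel

        F = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]])
        lam = np.array([1.0, -0.5])
        scores = F @ lam  # [1.0, 0.25, -0.5]
        z = np.exp(scores).sum()
        raw_expect = np.exp(scores) / z
        q = raw_expect
        entropy = -(q * np.log(q)).sum()
        fs = FeatureSet(
            variables=("a", "b"), classes=("L",),
            mins=np.zeros(2), maxs=np.ones(2),
            descriptors=[("L", 0), ("L", 1)],
        )
        model = MaxEntModel(
            features=fs, lambdas=lam, log_partition=np.log(z), entropy=entropy
        )
        assert predict_raw(model, F) == pytest.approx(raw_expect, abs=1e-12)
        c = np.exp(entropy)
        logi_expect = c * raw_expect / (1 + c * raw_expect)
        assert predict_logistic(model, F) == pytest.approx(logi_expect, abs=1e-12)

    def test_logistic_monotone_in_raw(self):
        env, bg, pr = make_instance(seed=13)
        fs, F = expand_features(env, {"L", "Q"}, background_rows=bg)
        model = fit_maxent(pr, bg, F, rm=0.5, features=fs)
        raw = predict_raw(model, F[bg])
        logi = predict_logistic(model, F[bg])
        order = np.argsort(raw)
        assert np.all(np.diff(logi[order]) >= 0)


class TestAicc:
    def test_zero_parameter_model_uniform_likelihood(self):
        env, bg, pr = make_instance(seed=15)
        fs, F = expand_features(env, {"L"}, background_rows=bg)
        model = fit_maxent(pr, bg, F, rm=1e6, features=fs)  # all lambdas zero
        n, N = len(pr), len(bg)
        assert compute_aicc(model, F[pr], F[bg]) == pytest.approx(
            -2 * n * np.log(1 / N), rel=1e-12
        )

    def test_zero_coefficient_features_not_counted(self):
        from bftb_sdm.maxent import FeatureSet, MaxEntModel

        fs = FeatureSet(
            variables=("a", "b"), classes=("L",),
            mins=np.zeros(2), maxs=np.ones(2),
            descriptors=[("L", 0), ("L", 1)],
        )
        F_study = np.array([[0.0, 0.3], [0.5, 0.1], [1.0, 0.9], [0.2, 0.4]])
        F_pres = F_study[:2]
        m1 = MaxEntModel(features=fs, lambdas=np.array([2.0, 0.0]))
        m2 = MaxEntModel(features=fs, lambdas=np.array([2.0, 1e-15]))
        assert m1.n_params == 1
        assert compute_aicc(m1, F_pres, F_study) == compute_aicc(m2, F_pres, F_study)

    def test_worked_two_presence_four_cell_example(self):
        from bftb_sdm.maxent import FeatureSet, MaxEntModel

        fs = FeatureSet(
            variables=("a",), classes=("L",),
            mins=np.zeros(1), maxs=np.ones(1), descriptors=[("L", 0)],
        )
        lam = 1.0
        F_study = np.array([[0.0], [0.25], [0.5], [1.0]])
        F_pres = np.array([[0.5], [1.0]])
        z = np.exp(F_study * lam).sum()
        lnl = (0.5 * lam - np.log(z)) + (1.0 * lam - np.log(z))
        k, n = 1, 2
        # n - k - 1 = 0 -> correction blows up -> +inf by convention
        model = MaxEntModel(features=fs, lambdas=np.array([lam]))
        assert compute_aicc(model, F_pres, F_study) == np.inf
        # with 4 presences the formula is finite and hand-checkable
        F_pres4 = np.array([[0.5], [1.0], [0.0], [0.25]])
        lnl4 = (F_pres4.sum() * lam - 4 * np.log(z))
        want = 2 * k - 2 * lnl4 + 2 * k * (k + 1) / (4 - k - 1)
        assert compute_aicc(model, F_pres4, F_study) == pytest.approx(want, rel=1e-12)


class TestAuc:
    def test_perfect_separation(self):
        assert evaluate_auc([0.9, 0.8], [0.2, 0.1]) == 1.0

    def test_identical_scores_half(self):
        assert evaluate_auc([0.5, 0.5], [0.5, 0.5]) == 0.5

    def test_tabulated_tie_case(self):
        # pairs: (.9,.8)=1 (.9,.1)=1 (.8,.8)=.5 (.8,.1)=1 -> 3.5/4
        assert evaluate_auc([0.9, 0.8], [0.8, 0.1]) == pytest.approx(0.875)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evaluate_auc([], [0.5])


class TestThresholds:
    def test_ten_values(self):
        vals = np.arange(1, 11) / 10.0
        mtp, p10 = compute_thresholds(vals)
        assert mtp == pytest.approx(0.1)
        assert p10 == pytest.approx(0.1)  # ceil(0.1*10) = 1st smallest

    def test_twenty_values(self):
        vals = 0.05 * np.arange(1, 21)
        mtp, p10 = compute_thresholds(vals)
        assert mtp == pytest.approx(0.05)
        assert p10 == pytest.approx(0.10)  # ceil(0.1*20) = 2nd smallest

    def test_all_equal(self):
        mtp, p10 = compute_thresholds([0.4, 0.4, 0.4])
        assert mtp == p10 == 0.4

    def test_mtp_never_exceeds_p10(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vals = rng.uniform(0, 1, rng.integers(1, 40))
            mtp, p10 = compute_thresholds(vals)
            assert mtp <= p10
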