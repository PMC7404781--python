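import numpy as np
import pytest
from scipy import stats

from specocc.ddsimca import (
    DDSIMCAError,
    DDSIMCAModel,
    DegenerateDataError,
    _moments_dof,
    _robust_dof,
    classify_ddsimca,
    extreme_plot,
    fit_ddsimca,
    select_pcs_by_target_sensitivity,
    total_distance,
)
from specocc.preprocess import snv
from specocc.synthetic import generate_pure_test, preset_design

from conftest import make_set


def low_rank_set(rng, n=60, p=40, sds=(6.0, 3.0, 1.5)):
    k = len(sds)
    basis = np.linalg.qr(rng.standard_normal((p, k)))[0]
    scores = rng.standard_normal((n, k)) * np.asarray(sds)
    return make_set(scores @ basis.T)


class TestFit:
    def test_subspace_data_reports_degeneracy(self, rng):
        sset = low_rank_set(rng)
        model = fit_ddsimca(sset, 3)
        assert model.degenerate_v
        assert np.max(model.train_v) < 1e-16

    def test_requested_k_clipped_to_rank(self, rng):
        sset = low_rank_set(rng)
        model = fit_ddsimca(sset, 7)
        assert model.k == 3 and model.k_requested == 7

    def test_moments_estimator_recovers_chisquare_dof(self, rng):
        h = 2.5 * rng.chisquare(4, 100_000) / 4
        center, n_hat = _moments_dof(h, "h")
        assert abs(n_hat - 4) < 0.15
        assert abs(center - 2.5) < 0.05

    def test_robust_estimator_agrees_on_clean_data(self, rng):
        h = 1.3 * rng.chisquare(6, 100_000) / 6
        center, n_hat = _robust_dof(h, "h")
        assert abs(n_hat - 6) < 0.3
        assert abs(center - 1.3) < 0.05

    def test_threshold_ordering_at_defaults(self, rng):
        sset = make_set(rng.standard_normal((100, 60)))
        model = fit_ddsimca(sset, 4, alpha=0.01, gamma=0.01)
        assert model.c_out > model.c_crit > 0

    def test_mean_score_distance_identity(self, rng):
        # with ddof-1 eigenvalues, sum(h) = k(n-1) exactly
        for n, p, k in [(37, 50, 6), (80, 20, 3)]:
            sset = make_set(rng.standard_normal((n, p)))
            model = fit_ddsimca(sset, k)
            assert abs(model.train_h.mean() - k * (n - 1) / n) < 1e-8

    def test_zero_variance_distance_raises_dof_error(self):
        with pytest.raises(DegenerateDataError, match="robust"):
            _moments_dof(np.full(50, 2.0), "h")

    def test_k_out_of_range(self, rng):
        sset = make_set(rng.standard_normal((10, 5)))
        with pytest.raises(DDSIMCAError):
            fit_ddsimca(sset, 10)

    def test_rounded_dof_mode(self, rng):
        sset = make_set(rng.standard_normal((100, 60)))
        model = fit_ddsimca(sset, 4, round_dof=True)
        assert model.N_h == round(model.N_h)
        assert 1 <= model.N_h <= 250


class TestClassify:
    def test_training_mean_is_regular_with_zero_distances(self, rng):
        sset = make_set(rng.standard_normal((50, 30)))
        model = fit_ddsimca(sset, 3)
        mean_sample = make_set([model.mean_spectrum])
        rec = classify_ddsimca(model, mean_sample)
        assert rec.loc[0, "h"] < 1e-20 and rec.loc[0, "v"] < 1e-20
        assert rec.loc[0, "category"] == "regular"

    def test_training_samples_reproduce_fit_distances(self, rng):
        sset = make_set(rng.standard_normal((50, 30)))
        model = fit_ddsimca(sset, 3)
        rec = classify_ddsimca(model, sset)
        np.testing.assert_allclose(rec["h"], model.train_h, atol=1e-10)
        np.testing.assert_allclose(rec["v"], model.train_v, atol=1e-10)

    def test_sample_order_invariance(self, rng):
        sset = make_set(rng.standard_normal((40, 25)))
        model = fit_ddsimca(sset, 3)
        perm = rng.permutation(40)
        rec = classify_ddsimca(model, sset).iloc[perm].reset_index(drop=True)
        rec_perm = classify_ddsimca(model, sset.take(perm))
        np.testing.assert_allclose(rec["c"], rec_perm["c"])

    def test_translation_invariance_after_refit(self, rng):
        X = rng.standard_normal((40, 25))
        shift = rng.standard_normal(25)
        m1 = fit_ddsimca(make_set(X), 3)
        m2 = fit_ddsimca(make_set(X + shift), 3)
        np.testing.assert_allclose(m1.train_h, m2.train_h, atol=1e-8)
        np.testing.assert_allclose(m1.train_v, m2.train_v, atol=1e-8)

    def test_axis_mismatch_rejected(self, rng):
        sset = make_set(rng.standard_normal((20, 10)))
        model = fit_ddsimca(sset, 2)
        other = make_set(rng.standard_normal((5, 10)),
                         wavenumbers=np.arange(10) + 0.5)
        with pytest.raises(DDSIMCAError, match="axis"):
            classify_ddsimca(model, other)

    def test_total_distance_monotone_in_h_and_v(self, rng):
        sset = make_set(rng.standard_normal((50, 30)))
        model = fit_ddsimca(sset, 3)
        h = np.linspace(0, 5, 11)
        assert np.all(np.diff(total_distance(model, h, np.zeros(11))) >= 0)
        assert np.all(np.diff(total_distance(model, np.zeros(11), h)) >= 0)

    def test_type_one_rate_within_binomial_envelope(self):
        """Pure samples from the study generator are rejected at ~alpha."""
        design = preset_design("separable", seed=3)
        cal = snv(generate_pure_test(design, n=1500, seed_offset=21))
        test = snv(generate_pure_test(design, n=1000, seed_offset=23))
        model = fit_ddsimca(cal, 4, alpha=0.01)
        rej = 1 - classify_ddsimca(model, test)["accepted"].mean()
        lo = stats.binom.ppf(0.005, 1000, 0.01) / 1000
        hi = stats.binom.ppf(0.995, 1000, 0.01) / 1000
        assert lo <= rej <= hi


class TestSelection:
    def test_single_candidate_returned(self, rng):
        sset = make_set(rng.standard_normal((30, 20)))
        sel = select_pcs_by_target_sensitivity(sset, k_candidates=[1], seed=0)
        assert sel.chosen_k == 1

    def test_flat_curve_on_low_rank_data(self, rng):
        """Well-specified low-rank data: CV acceptance is at ceiling for
        every k (the chi-square acceptance self-calibrates), equal from the
        true rank on, and the parsimony rule picks the smallest candidate."""
        sset = low_rank_set(rng, n=90, p=40)
        sel = select_pcs_by_target_sensitivity(sset, k_candidates=range(1, 11),
                                               folds=5, seed=0)
        acc = np.asarray(sel.acceptance)
        best = np.nanmax(acc)
        se = np.sqrt(best * (1 - best) / sel.n_eval)
        assert np.all(acc >= best - se)           # flat within one SE
        assert np.allclose(acc[2:], acc[2])       # identical from the rank on
        assert sel.chosen_k == sel.candidates[np.argmax(acc >= best - se)]

    def test_all_degenerate_candidates_raise(self):
        sset = make_set(np.ones((20, 10)))
        with pytest.raises(DDSIMCAError):
            select_pcs_by_target_sensitivity(sset, k_candidates=[1, 2], seed=0)


class TestExtremePlot:
    def test_alpha_one_counts_every_sample(self, rng):
        sset = make_set(rng.standard_normal((50, 30)))
        model = fit_ddsimca(sset, 3)
        ep = extreme_plot(model, sset, alpha_grid=np.array([1.0]))
        assert ep.observed[0] == 50

    def test_tiny_alpha_counts_none(self, rng):
        sset = make_set(rng.standard_normal((50, 30)))
        model = fit_ddsimca(sset, 3)
        ep = extreme_plot(model, sset, alpha_grid=np.array([1e-12]))
        assert ep.observed[0] == 0

    def test_observed_monotone_in_alpha(self, rng):
        sset = make_set(rng.standard_normal((80, 40)))
        model = fit_ddsimca(sset, 4)
        ep = extreme_plot(model, sset)
        order = np.argsort(ep.alpha_grid)
        assert np.all(np.diff(ep.observed[order]) >= 0)

    def test_calibration_over_many_seeds(self):
        """>=90% of grid points inside the 95% binomial envelope on
        well-specified data, aggregated over 200 independent fits."""
        inside = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            basis = np.linalg.qr(rng.standard_normal((30, 3)))[0]
            X = (rng.standard_normal((100, 3)) * [5, 3, 2]) @ basis.T
            X += 0.3 * rng.standard_normal((100, 30))
            sset = make_set(X)
            model = fit_ddsimca(sset, 3, alpha=0.05)
            ep = extreme_plot(model, sset)
            ok = (ep.observed >= ep.tolerance_low) & (ep.observed <= ep.tolerance_high)
            inside.append(ok.mean())
        assert np.mean(inside) >= 0.90


class TestSerialization:
    def test_json_round_trip(self, rng, tmp_path):
        sset = make_set(rng.standard_normal((40, 25)))
        model = fit_ddsimca(sset, 3)
        path = model.to_json(tmp_path / "m.json")
        back = DDSIMCAModel.from_json(path)
        rec1 = classify_ddsimca(model, sset)
        rec2 = classify_ddsimca(back, sset)
        np.testing.assert_allclose(rec1["c"], rec2["c"])
        assert list(rec1["category"]) == list(rec2["category"])
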