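import numpy as np
import pandas as pd
import pytest

import epiclock as ec
from epiclock.model import (
    _Design,
    _fast_objective,
    _f_statistic,
    _objective_value,
    _predict,
)
from conftest import TIME_TRIPLES, analytic_dataset


class TestObjective:
    def test_perfect_fit_is_zero(self, clonal_noisefree_data):
        spec, params, data = clonal_noisefree_data
        assert ec.objective(params, spec, data) == pytest.approx(0.0, abs=1e-18)

    def test_residual_term_hand_value(self, clonal_noisefree_data):
        # shift two divergences by (0, +0.05): objective gains 0.05^2
        spec, params, data = clonal_noisefree_data
        d = data.pairs["D"].to_numpy().copy()
        d[1] += 0.05
        shifted = data.replace_divergence(d)
        assert ec.objective(params, spec, shifted) == pytest.approx(0.05**2)

    def test_equilibrium_constraint_term(self, clonal_noisefree_data):
        # offsetting p_bar_1 by 0.1 adds M * 0.1^2 on top of the residual term
        spec, params, data = clonal_noisefree_data
        data_off = ec.DivergenceDataset(
            data.pairs.copy(), data.p1_obs, data.p3_obs, data.p_bar_1 + 0.1
        )
        base = ec.objective(params, spec, data)
        assert ec.objective(params, spec, data_off) - base == pytest.approx(
            data.M * 0.01, rel=1e-9
        )

    def test_invariant_under_pair_permutation(self, clonal_noisefree_data):
        spec, params, data = clonal_noisefree_data
        rng = np.random.default_rng(0)
        perm = data.pairs.sample(frac=1.0, random_state=1).reset_index(drop=True)
        permuted = ec.DivergenceDataset(perm, data.p1_obs, data.p3_obs, data.p_bar_1)
        assert ec.objective(params, spec, permuted) == pytest.approx(
            ec.objective(params, spec, data), abs=1e-15
        )

    def test_fast_path_matches_reference(self, clonal_noisefree_data):
        _, _, data = clonal_noisefree_data
        design = _Design(data)
        rng = np.random.default_rng(3)
        for system in ("selfing", "clonal"):
            for form in ("ABneutral", "ABmm", "ABuu"):
                spec = ec.ModelSpec(system, form)
                for _ in range(20):
                    a, b = 10 ** rng.uniform(-6, -1, 2)
                    w = rng.uniform(0.3, 0.999)
                    g = rng.uniform(0.05, 0.95)
                    c = rng.uniform(0.0, 0.05)
                    ref = _objective_value(
                        design, spec, ec.EpimutationParams(a, b, w=w, gamma=g, c=c)
                    )
                    fast = _fast_objective(design, spec, a, b, w, g, c)
                    if fast is not None:
                        assert fast == pytest.approx(ref, rel=1e-3, abs=1e-12)


class TestFit:
    def test_noise_free_self_consistency(self, clonal_noisefree_data):
        # clonal alpha=5e-3, beta=2e-2, c=0.01: exact recovery from exact data
        spec, params, data = clonal_noisefree_data
        res = ec.EpimutationModel(data, spec).fit(n_starts=10, seed=1)
        assert res.params.alpha == pytest.approx(params.alpha, rel=0.01)
        assert res.params.beta == pytest.approx(params.beta, rel=0.01)
        assert res.rss < 1e-10
        assert res.df_resid == data.M - 4

    def test_abnull_intercept_only_closed_form(self, clonal_noisefree_data):
        spec, _, data = clonal_noisefree_data
        res = ec.EpimutationModel(data, ec.ModelSpec("clonal", "ABnull")).fit(n_starts=1)
        d = data.pairs["D"].to_numpy()
        assert res.params.c == pytest.approx(d.mean(), abs=1e-15)
        assert res.rss == pytest.approx(np.sum((d - d.mean()) ** 2), abs=1e-15)
        assert res.df_resid == data.M - 1

    def test_deterministic_given_seed(self, clonal_noisefree_data):
        spec, _, data = clonal_noisefree_data
        r1 = ec.EpimutationModel(data, spec).fit(n_starts=4, seed=7)
        r2 = ec.EpimutationModel(data, spec).fit(n_starts=4, seed=7)
        assert r1.params == r2.params
        assert r1.rss == r2.rss
        assert np.array_equal(r1.resid, r2.resid)

    def test_too_few_pairs_rejected(self):
        spec = ec.ModelSpec("clonal", "ABneutral")
        params = ec.EpimutationParams(1e-3, 4e-3, c=0.0)
        data = analytic_dataset(spec, params, TIME_TRIPLES[:4], 0.6, 0.3)
        with pytest.raises(ValueError, match="free parameters"):
            ec.EpimutationModel(data, spec).fit(n_starts=1)

    def test_nested_objective_monotonicity(self):
        # ABnull ⊆ ABneutral ⊆ ABuu: more free parameters never fit worse
        spec = ec.ModelSpec("clonal", "ABneutral")
        params = ec.EpimutationParams(2e-3, 6e-3, c=0.005)
        data = analytic_dataset(spec, params, TIME_TRIPLES, 0.6, 0.3)
        rng = np.random.default_rng(5)
        noisy = data.replace_divergence(
            np.clip(data.pairs["D"].to_numpy() + rng.normal(0, 2e-3, data.M), 0, 1)
        )
        opts = ec.FitOptions(n_starts=8, seed=2)
        rss = {}
        for form in ("ABnull", "ABneutral", "ABuu"):
            rss[form] = ec.EpimutationModel(noisy, ec.ModelSpec("clonal", form)).fit(opts).rss
        assert rss["ABneutral"] <= rss["ABnull"] + 1e-8
        assert rss["ABuu"] <= rss["ABneutral"] + 1e-8

    def test_summary_mentions_estimates(self, clonal_noisefree_data):
        spec, _, data = clonal_noisefree_data
        res = ec.EpimutationModel(data, spec).fit(n_starts=2, seed=0)
        text = res.summary()
        assert "alpha" in text and "RSS" in text and "ABneutral" in text


class TestFTest:
    def test_formula_hand_value(self):
        # RSS_R=2, RSS_F=1, df_R=11, df_F=10 -> F = ((2-1)/1)/(1/10) = 10
        f, df_num, df_den = _f_statistic(2.0, 1.0, 11, 10)
        assert (f, df_num, df_den) == (10.0, 1, 10)

    def test_identical_fits_give_f_zero(self, clonal_noisefree_data):
        spec, _, data = clonal_noisefree_data
        opts = ec.FitOptions(n_starts=6, seed=3)
        full = ec.EpimutationModel(data, ec.ModelSpec("clonal", "ABuu")).fit(opts)
        red = ec.EpimutationModel(data, spec).fit(opts)
        ft = full.compare_f_test(red)
        # noise-free data: both rss ~ 0; statistic may clamp at 0
        assert ft.F >= 0.0
        assert 0.0 <= ft.p_value <= 1.0
        assert ft.df_num == 1

    def test_not_nested_rejected(self, clonal_noisefree_data):
        spec, _, data = clonal_noisefree_data
        opts = ec.FitOptions(n_starts=2, seed=0)
        mm = ec.EpimutationModel(data, ec.ModelSpec("clonal", "ABmm")).fit(opts)
        uu = ec.EpimutationModel(data, ec.ModelSpec("clonal", "ABuu")).fit(opts)
        with pytest.raises(ValueError, match="nested"):
            ec.compare_models(mm, uu)

    def test_null_vs_neutral_detects_accumulation(self):
        spec = ec.ModelSpec("clonal", "ABneutral")
        params = ec.EpimutationParams(2e-3, 6e-3, c=0.005)
        data = analytic_dataset(spec, params, TIME_TRIPLES, 0.6, 0.3)
        rng = np.random.default_rng(8)
        noisy = data.replace_divergence(
            np.clip(data.pairs["D"].to_numpy() + rng.normal(0, 5e-4, data.M), 0, 1)
        )
        opts = ec.FitOptions(n_starts=8, seed=1)
        full = ec.EpimutationModel(noisy, spec).fit(opts)
        red = ec.EpimutationModel(noisy, ec.ModelSpec("clonal", "ABnull")).fit(opts)
        ft = ec.compare_models(full, red)
        assert ft.df_num == 3
        assert ft.p_value < 0.01  # strong real accumulation signal


class TestBootstrap:
    def test_deterministic_replicates(self, clonal_noisefree_data):
        spec, _, data = clonal_noisefree_data
        rng = np.random.default_rng(2)
        noisy = data.replace_divergence(
            np.clip(data.pairs["D"].to_numpy() + rng.normal(0, 1e-3, data.M), 0, 1)
        )
        res = ec.EpimutationModel(noisy, spec).fit(n_starts=4, seed=0)
        b1 = res.bootstrap(B=20, seed=11)
        b2 = res.bootstrap(B=20, seed=11)
        pd.testing.assert_frame_equal(b1.replicate_estimates, b2.replicate_estimates)

    def test_degenerate_residuals_give_zero_width(self, clonal_noisefree_data):
        spec, _, data = clonal_noisefree_data
        res = ec.EpimutationModel(data, spec).fit(n_starts=6, seed=1)
        assert res.rss < 1e-12
        bs = res.bootstrap(B=10, seed=0)
        for lo, hi in bs.intervals.values():
            assert hi - lo < 1e-6

    def test_interval_contains_point_estimate_on_noisy_data(self, clonal_noisefree_data):
        spec, _, data = clonal_noisefree_data
        rng = np.random.default_rng(4)
        noisy = data.replace_divergence(
            np.clip(data.pairs["D"].to_numpy() + rng.normal(0, 1e-3, data.M), 0, 1)
        )
        res = ec.EpimutationModel(noisy, spec).fit(n_starts=4, seed=0)
        bs = res.bootstrap(B=100, seed=3)
        lo, hi = bs.intervals["alpha"]
        assert lo <= res.params.alpha * 1.05 and hi >= res.params.alpha * 0.95

    def test_b_must_be_positive(self, clonal_noisefree_data):
        spec, _, data = clonal_noisefree_data
        res = ec.EpimutationModel(data, spec).fit(n_starts=2, seed=0)
        with pytest.raises(ValueError):
            res.bootstrap(B=0)


class TestAgeProfile:
    def build_tree_samples(self):
        spec = ec.ModelSpec("clonal", "ABneutral")
        params = ec.EpimutationParams(2e-4, 6e-4)
        pi = ec.equilibrium_founder(spec, params)
        ped = ec.two_stem_tree(100.0, (60, 30), (50, 20))
        cfg = ec.SimulationConfig(spec, params, 30_000, pi, 1e-3, 13)
        samples = ec.evolve_pedigree(ped, cfg, step_mode="edge")
        return spec, list(samples.values())

    def test_single_candidate_grid(self):
        spec, samples = self.build_tree_samples()
        prof = ec.profile_founder_age(
            lambda a: ec.two_stem_tree(a, (60, 30), (50, 20)),
            samples, spec, [100.0], ec.FitOptions(n_starts=3, seed=0),
        )
        assert prof.age_hat == 100.0
        assert len(prof.fits) == 1
        assert np.isfinite(prof.lsq).all()

    def test_empty_grid_rejected(self):
        spec, samples = self.build_tree_samples()
        with pytest.raises(ValueError, match="empty"):
            ec.profile_founder_age(
                lambda a: ec.two_stem_tree(a, (60, 30), (50, 20)), samples, spec, []
            )

    def test_recovers_true_age_coarsely(self):
        spec, samples = self.build_tree_samples()
        grid = [70.0, 100.0, 130.0]
        prof = ec.profile_founder_age(
            lambda a: ec.two_stem_tree(a, (60, 30), (50, 20)),
            samples, spec, grid, ec.FitOptions(n_starts=3, seed=0),
        )
        assert prof.age_hat == 100.0


def test_model_from_samples_end_to_end():
    ped = ec.ma_pedigree(3, [10, 20])
    spec = ec.ModelSpec("selfing", "ABneutral")
    params = ec.EpimutationParams(5e-3, 1.5e-2)
    cfg = ec.SimulationConfig(
        spec, params, 20_000, ec.equilibrium_founder(spec, params), 1e-3, 21
    )
    samples = ec.evolve_pedigree(ped, cfg)
    model = ec.EpimutationModel.from_samples(
        ped, list(samples.values()), founder_sample="S_F",
        system="selfing", form="ABneutral",
    )
    res = model.fit(n_starts=4, seed=0)
    assert res.nobs == 7 * 6 // 2
    assert np.isfinite(res.rss)
    assert res.params.alpha == pytest.approx(params.alpha, rel=0.5)
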