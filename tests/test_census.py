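import numpy as np
import pandas as pd
import pytest

from microcensus import (
    CensusModel,
    OtuTable,
    build_null,
    density_at,
    estimate_population,
    fit_reference,
    sample_mixtures,
    t_statistic,
)
from microcensus.census import TStatNull, _silverman_bandwidth
from microcensus.datamodel import to_relative
from microcensus.reference import ReferenceModel


def _model(mu, sigma, ids=None):
    ids = ids or [f"f{i}" for i in range(len(mu))]
    return ReferenceModel(ids, np.asarray(mu), np.asarray(sigma), n0=100)


class TestTStatistic:
    def test_zero_at_the_mean(self):
        model = _model([0.5, 0.5], [0.1, 0.2])
        assert t_statistic(np.array([0.5, 0.5]), model) == 0.0

    def test_hand_arithmetic(self):
        model = _model([0.5, 0.5], [0.1, 0.2])
        assert t_statistic(np.array([0.6, 0.3]), model) == pytest.approx(2.0)

    def test_missing_feature_listed(self):
        model = _model([0.5, 0.5], [0.1, 0.2], ids=["A", "B"])
        with pytest.raises(ValueError, match="B"):
            t_statistic(pd.Series({"A": 0.5}), model)

    def test_series_reordered_to_features(self):
        model = _model([0.5, 0.5], [0.1, 0.2], ids=["A", "B"])
        forward = t_statistic(pd.Series({"A": 0.6, "B": 0.3}), model)
        reordered = t_statistic(pd.Series({"B": 0.3, "A": 0.6}), model)
        assert forward == reordered == pytest.approx(2.0)

    def test_equals_hotelling_form_for_diagonal_covariance(self):
        # with independent coordinates the full Hotelling statistic built
        # from the inverse covariance matrix reduces to n * T
        rng = np.random.default_rng(0)
        n0, p, n = 4000, 3, 8
        x = rng.normal([0.2, 0.5, 0.3], [0.02, 0.05, 0.04], size=(n0, p))
        mu = x.mean(axis=0)
        sigma2 = x.var(axis=0)
        model = _model(mu, np.sqrt(sigma2))
        w = x[:n].mean(axis=0)
        t = t_statistic(w, model)
        cov_diag = np.diag(sigma2)
        hotelling = n * (w - mu) @ np.linalg.inv(cov_diag) @ (w - mu)
        assert n * t == pytest.approx(hotelling, rel=1e-10)

    def test_scale_invariance(self, small_table):
        # multiplying a taxon's column by c > 0 in cohort and query leaves T
        # unchanged because sigma_hat rescales with it
        features = small_table.taxon_ids[:5]
        model = fit_reference(small_table, features)
        w = small_table.values[0, :5].copy()
        t1 = t_statistic(w, model)
        c = 0.25
        x = small_table.data.loc[:, features].to_numpy().copy()
        x[:, 0] *= c
        model2 = ReferenceModel(
            features, x.mean(axis=0), x.std(axis=0), small_table.n_samples
        )
        w2 = w.copy()
        w2[0] *= c
        assert t_statistic(w2, model2) == pytest.approx(t1, rel=1e-9)


class TestDensity:
    def test_kde_integrates_to_one(self):
        rng = np.random.default_rng(1)
        samples = rng.gamma(3.0, 1.0, size=500)
        null = TStatNull(1, samples, _silverman_bandwidth(samples), "plain_bootstrap")
        grid = np.linspace(-10, 40, 20001)
        dens = np.array([density_at(null, t) for t in grid[::40]])
        integral = np.trapezoid(dens, grid[::40])
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_symmetric_two_point_sample(self):
        samples = np.array([1.0, 3.0] * 50)
        null = TStatNull(1, samples, 0.5, "plain_bootstrap")
        assert density_at(null, 1.0) == pytest.approx(density_at(null, 3.0))

    def test_density_higher_at_median_than_far_tail(self):
        rng = np.random.default_rng(2)
        samples = rng.normal(10, 1, size=1000)
        null = TStatNull(1, samples, _silverman_bandwidth(samples), "plain_bootstrap")
        med = float(np.median(samples))
        far = float(samples.max() + 5 * null.bandwidth)
        assert density_at(null, med) > density_at(null, far)

    def test_degenerate_sample_falls_back_to_floor(self):
        h = _silverman_bandwidth(np.full(200, 2.5))
        assert h == 1e-12


class TestBuildNull:
    def test_n1_samples_come_from_empirical_multiset(self, small_model, small_table):
        census = build_null(small_model, small_table, N=1, B=300, seed=0)
        empirical = {
            round(t_statistic(pd.Series(row, index=small_table.taxon_ids),
                              small_model), 10)
            for row in small_table.values
        }
        for t in census.null_for(1).t_samples:
            assert round(float(t), 10) in empirical

    def test_median_decreases_with_n(self, small_census):
        medians = [
            np.median(small_census.null_for(n).t_samples) for n in (1, 5, 25, 60)
        ]
        assert all(a > b for a, b in zip(medians, medians[1:]))

    def test_subsample_corrected_requires_small_N(self, small_model, small_table):
        with pytest.raises(ValueError, match="N < n0"):
            build_null(
                small_model,
                small_table,
                N=small_table.n_samples,
                B=100,
                mode="subsample_corrected",
            )

    def test_mean_nt_close_to_p_with_true_parameters(self):
        # with independent standardized coordinates and the TRUE mean and
        # standard deviation supplied, E[n T_n] = p exactly
        rng = np.random.default_rng(3)
        n0, p = 3000, 12
        raw = rng.gamma(2.0, 0.5, size=(n0, p))
        mu, sd = 2.0 * 0.5, np.sqrt(2.0) * 0.5
        model = ReferenceModel(
            [f"f{i}" for i in range(p)],
            np.full(p, min(mu, 1.0)),
            np.full(p, sd),
            n0,
        )
        data = pd.DataFrame(raw, columns=model.feature_ids)
        # synthetic coordinates are not compositional; normalize the
        # is_relative contract away by scaling rows (T is scale-invariant
        # per taxon, so the math is unchanged when we standardize directly)
        table = OtuTable(data, is_relative=False)
        table.is_relative = True  # raw coordinates stand in for proportions
        cm = build_null(model, table, N=30, B=4000, seed=4)
        for n in (5, 30):
            nt = n * cm.null_for(n).t_samples
            se = nt.std() / np.sqrt(nt.size)
            assert abs(nt.mean() - p) < 4 * se

    def test_determinism(self, small_model, small_table):
        a = build_null(small_model, small_table, N=10, B=200, seed=5)
        b = build_null(small_model, small_table, N=10, B=200, seed=5)
        for n in range(1, 11):
            np.testing.assert_array_equal(
                a.null_for(n).t_samples, b.null_for(n).t_samples
            )


class TestEstimate:
    def test_single_candidate_returns_it(self, small_model, small_table):
        census = build_null(small_model, small_table, N=1, B=200, seed=6)
        w = small_table.values[0, :]
        est = estimate_population(
            pd.Series(w, index=small_table.taxon_ids), census
        )
        assert est.n_hat == 1
        assert est.ci[0] == 1

    def test_grand_mean_maps_to_largest_candidate(self, small_census, small_table):
        # the cohort grand mean equals mu_hat exactly, the maximally mixed
        # degenerate case: the most-mixed candidate N is reported
        grand = small_table.data.mean(axis=0)
        est = estimate_population(grand, small_census)
        assert est.n_hat == small_census.N

    def test_heavily_mixed_query_maps_to_large_n(self, small_census, small_table):
        # near-zero (but nonzero) statistic: likelihood must favor large n
        batch = sample_mixtures(
            small_table, n=small_census.N, reps=20,
            scheme="without_replacement", seed=17,
        )
        n_hats = [
            estimate_population(
                pd.Series(row, index=small_table.taxon_ids), small_census
            ).n_hat
            for row in batch.values
        ]
        assert np.median(n_hats) >= small_census.N * 0.4

    def test_t0_zero_degeneracy(self, small_census):
        mu = pd.Series(
            small_census.reference.mu_hat, index=small_census.reference.feature_ids
        )
        est = estimate_population(mu, small_census)
        assert est.t0 == 0.0
        assert est.ci == (1, float(small_census.N))

    def test_estimate_deterministic(self, small_census, small_table):
        w = pd.Series(
            sample_mixtures(small_table, 10, 1, seed=8).values[0],
            index=small_table.taxon_ids,
        )
        a = estimate_population(w, small_census)
        b = estimate_population(w, small_census)
        assert a.n_hat == b.n_hat and a.t0 == b.t0 and a.ci == b.ci

    def test_loglik_has_length_N(self, small_census, small_table):
        w = pd.Series(
            sample_mixtures(small_table, 5, 1, seed=9).values[0],
            index=small_table.taxon_ids,
        )
        est = estimate_population(w, small_census)
        assert est.loglik.shape == (small_census.N,)
        assert 1 <= est.n_hat <= small_census.N


class TestSerialization:
    def test_save_load_round_trip(self, small_census, tmp_path):
        small_census.save(tmp_path / "census")
        again = CensusModel.load(tmp_path / "census")
        assert again.N == small_census.N and again.B == small_census.B
        assert again.mode == small_census.mode
        assert again.train_sample_ids == small_census.train_sample_ids
        np.testing.assert_allclose(
            again.null_for(3).t_samples, small_census.null_for(3).t_samples
        )
        assert again.null_for(3).bandwidth == pytest.approx(
            small_census.null_for(3).bandwidth
        )
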