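import numpy as np
import pytest
from scipy import stats as sps
from scipy.special import betainc

from nestperm.synthetic import (
    SimulationModel,
    coverage_study,
    generate_dataset,
    student_t_comparators,
    type_i_error_study,
)


class TestGenerateDataset:
    def test_three_level_layout(self):
        m = SimulationModel(clusters_per_group=4, obs_per_cluster=3)
        dt = generate_dataset(m, seed=0)
        assert dt.level_names == ["Treatment", "Cluster", "Obs"]
        assert dt.n_rows == 2 * 4 * 3
        assert list(dt.data["Treatment"].unique()) == ["g0", "g1"]

    def test_four_level_layout(self):
        m = SimulationModel(n_blocks=3, clusters_per_group=3, obs_per_cluster=3)
        dt = generate_dataset(m, seed=0)
        assert dt.level_names == ["Block", "Treatment", "Cluster", "Obs"]
        assert dt.n_rows == 3 * 2 * 3 * 3
        assert m.treatment_level == 2

    def test_deterministic_under_seed(self):
        m = SimulationModel()
        a = generate_dataset(m, seed=42).response
        b = generate_dataset(m, seed=42).response
        np.testing.assert_array_equal(a, b)
        c = generate_dataset(m, seed=43).response
        assert not np.array_equal(a, c)

    def test_null_group_difference_centers_at_zero(self):
        m = SimulationModel(beta=0.0, clusters_per_group=4, obs_per_cluster=3)
        diffs = []
        for s in range(400):
            dt = generate_dataset(m, seed=s)
            y = dt.response
            g = dt.data["Treatment"].to_numpy()
            diffs.append(y[g == "g1"].mean() - y[g == "g0"].mean())
        # se of the pooled mean difference across 400 null datasets
        assert abs(np.mean(diffs)) < 4 * np.std(diffs) / np.sqrt(len(diffs))

    def test_beta_shifts_groups(self):
        m = SimulationModel(beta=3.0, clusters_per_group=50, obs_per_cluster=10)
        dt = generate_dataset(m, seed=1)
        y = dt.response
        g = dt.data["Treatment"].to_numpy()
        assert y[g == "g1"].mean() - y[g == "g0"].mean() == pytest.approx(3.0, abs=0.5)

    @pytest.mark.parametrize("icc", [0.2, 0.5, 0.8])
    def test_empirical_icc_matches_nominal(self, icc):
        """Variance-components oracle: between-cluster share of total noise
        variance equals the nominal intraclass correlation."""
        m = SimulationModel(
            beta=0.0, clusters_per_group=6, obs_per_cluster=8, icc=icc
        )
        n_obs = m.obs_per_cluster
        msb_list, msw_list = [], []
        for s in range(300):
            dt = generate_dataset(m, seed=s)
            y = dt.response.reshape(-1, n_obs)  # one row per cluster
            cluster_means = y.mean(axis=1)
            msw_list.append(np.mean(y.var(axis=1, ddof=1)))
            msb_list.append(n_obs * cluster_means.var(ddof=1))
        msw = np.mean(msw_list)
        msb = np.mean(msb_list)
        var_between = (msb - msw) / n_obs
        est_icc = var_between / (var_between + msw)
        assert est_icc == pytest.approx(icc, abs=0.05)

    def test_lognormal_individuals_are_right_skewed(self):
        m = SimulationModel(
            beta=0.0, clusters_per_group=200, obs_per_cluster=5,
            individual_dist="lognormal", icc=0.0,
        )
        y = generate_dataset(m, seed=2).response
        assert sps.skew(y) > 0.5

    @pytest.mark.parametrize(
        "fam,frozen",
        [
            ("lognormal", sps.lognorm(s=0.75)),
            ("pareto", sps.pareto(3.0)),
            ("gamma", sps.gamma(2.0)),
        ],
    )
    def test_families_standardized_with_analytic_moments(self, fam, frozen):
        """Each family is centered/scaled by its analytic mean and standard
        deviation (scipy as the independent oracle), giving unit variance by
        construction even for heavy-tailed draws."""
        from nestperm.synthetic import DISTRIBUTION_FAMILIES

        draws = DISTRIBUTION_FAMILIES[fam](np.random.default_rng(3), 5000, {})
        rng = np.random.default_rng(3)
        if fam == "lognormal":
            raw = rng.lognormal(0.0, 0.75, 5000)
        elif fam == "pareto":
            raw = rng.pareto(3.0, 5000) + 1.0
        else:
            raw = rng.gamma(2.0, 1.0, 5000)
        mean, var = frozen.stats(moments="mv")
        np.testing.assert_allclose(draws, (raw - mean) / np.sqrt(var), rtol=1e-12)

    def test_variance_ratio_scales_last_group(self):
        m = SimulationModel(
            beta=0.0, clusters_per_group=4000, obs_per_cluster=1,
            icc=0.0, variance_ratio=1.5,
        )
        dt = generate_dataset(m, seed=4)
        y = dt.response
        g = dt.data["Treatment"].to_numpy()
        ratio = y[g == "g1"].var() / y[g == "g0"].var()
        assert ratio == pytest.approx(1.5, abs=0.15)

    @pytest.mark.parametrize(
        "kw", [
            {"icc": 1.5},
            {"cluster_dist": "cauchy"},
            {"dist_params": {"pareto_shape": 1.5}, "cluster_dist": "pareto"},
        ],
    )
    def test_infeasible_models_rejected(self, kw):
        with pytest.raises(ValueError):
            generate_dataset(SimulationModel(**kw), seed=0)


class TestComparators:
    def test_identical_groups_give_p_one(self):
        p = student_t_comparators([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert p["student_t"] == pytest.approx(1.0)
        assert p["welch_t"] == pytest.approx(1.0)

    def test_swapping_groups_preserves_p(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=5), rng.normal(1, 1, size=5)
        p1 = student_t_comparators([a, b])
        p2 = student_t_comparators([b, a])
        assert p1["student_t"] == pytest.approx(p2["student_t"])

    def test_matches_incomplete_beta_cdf(self):
        """Cross-check the pooled t p-value against a direct incomplete-beta
        evaluation of the t distribution's tail."""
        a = np.array([1.2, 0.8, 1.9, 1.4])
        b = np.array([2.6, 3.1, 2.2, 2.9])
        p = student_t_comparators([a, b])["student_t"]
        n1, n2 = len(a), len(b)
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        t = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
        p_beta = betainc(df / 2, 0.5, df / (df + t ** 2))
        assert p == pytest.approx(p_beta, rel=1e-10)

    def test_paired_variant(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=6)
        b = a + rng.normal(0.5, 0.1, size=6)
        p = student_t_comparators([a, b], paired=True)
        assert "paired_t" in p and p["paired_t"] < 0.01

    def test_too_few_clusters_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            student_t_comparators([[1.0], [2.0, 3.0]])


class TestStudies:
    def test_alpha_one_rejects_everything(self):
        m = SimulationModel(beta=0.0, clusters_per_group=3, obs_per_cluster=2)
        res = type_i_error_study(
            m, n_datasets=20, alpha=1.0, bootstraps=10, permutations="all",
            seed=0, comparators=False,
        )
        assert res.rates["hierarchical"] == 1.0

    def test_requires_null_model(self):
        with pytest.raises(ValueError, match="beta = 0"):
            type_i_error_study(SimulationModel(beta=1.0), n_datasets=5)

    def test_study_frame_schema(self):
        m = SimulationModel(beta=0.0)
        res = type_i_error_study(
            m, n_datasets=30, bootstraps=20, permutations="all", seed=1
        )
        frame = res.to_frame()
        assert set(frame["method"]) == {"hierarchical", "student_t", "welch_t"}
        assert {"rate", "nominal_band_low", "nominal_band_high"} <= set(frame.columns)
        assert ((frame["rate"] >= 0) & (frame["rate"] <= 1)).all()

    def test_external_p_vectors_tabulated(self):
        m = SimulationModel(beta=0.0)
        res = type_i_error_study(
            m, n_datasets=10, bootstraps=5, permutations=20, seed=2,
            comparators=False, external_p={"lmm": np.linspace(0.01, 0.9, 10)},
        )
        assert res.counts["lmm"] == 1  # only 0.01 <= 0.05

    def test_coverage_guard_refuses_degenerate_level(self):
        m = SimulationModel(beta=1.0, clusters_per_group=3)  # 20 permutations
        with pytest.raises(Exception, match="achievable"):
            coverage_study(m, n_datasets=2, level=0.95, bootstraps=5,
                           permutations="all", seed=0)

    def test_coverage_invariant_to_location_shift(self):
        # shifting every response leaves interval coverage untouched
        from nestperm import confidence_interval
        from nestperm.synthetic import generate_dataset

        m = SimulationModel(beta=1.0, clusters_per_group=4, obs_per_cluster=3)
        dt = generate_dataset(m, seed=5)
        ci1 = confidence_interval(dt, 1, level=0.9, bootstraps=30,
                                  permutations="all", seed=9)
        shifted = dt.data.copy()
        shifted["y"] = shifted["y"] + 100.0
        ci2 = confidence_interval(shifted, 1, level=0.9, bootstraps=30,
                                  permutations="all", seed=9)
        np.testing.assert_allclose(ci1.lower, ci2.lower, atol=1e-8)
        np.testing.assert_allclose(ci1.upper, ci2.upper, atol=1e-8)

    def test_welch_conservative_on_doubly_nested_design(self):
        """With two nested levels (blocks above treatment), unpaired t tests
        on cluster means absorb the between-block variance into their error
        term and reject far less often than nominal."""
        m = SimulationModel(
            beta=0.0, n_blocks=3, clusters_per_group=3, obs_per_cluster=3,
            icc=0.5,
        )
        rng = np.random.default_rng(7)
        n, rejected = 1000, 0
        from nestperm.synthetic import _cluster_means

        for _ in range(n):
            dt = generate_dataset(m, seed=int(rng.integers(2 ** 31)))
            p = student_t_comparators(_cluster_means(dt, m))["welch_t"]
            rejected += p <= 0.05
        band_low = 0.05 - 1.96 * np.sqrt(0.05 * 0.95 / n)
        assert rejected / n < band_low

    def test_small_coverage_study_runs(self):
        m = SimulationModel(beta=1.0, clusters_per_group=4, obs_per_cluster=3)
        res = coverage_study(m, n_datasets=25, level=0.95, bootstraps=30,
                             permutations="all", seed=3)
        assert res.kind == "coverage"
        assert 0.6 <= res.rates["hierarchical"] <= 1.0
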