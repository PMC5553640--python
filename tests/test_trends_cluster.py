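import itertools

import numpy as np
import pandas as pd
import pytest

from trophoflow import (
    ahc_ward,
    apply_modality_rules,
    cluster_trajectories,
    default_modality_rules,
    enrich_modalities,
    hypergeom_enrichment,
    mean_trend_with_bootstrap,
    pca_trajectories,
    trend_significance,
)


class TestBootstrapTrend:
    def test_identical_rows_zero_width_ci(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]] * 5, columns=[2000, 2001, 2002])
        out = mean_trend_with_bootstrap(m, n_boot=200, seed=0)
        np.testing.assert_allclose(out["ci_low"], out["mean"])
        np.testing.assert_allclose(out["ci_high"], out["mean"])

    def test_two_ecosystem_resample_support(self):
        m = pd.DataFrame([[0.0] * 3, [1.0] * 3], columns=[2000, 2001, 2002])
        out = mean_trend_with_bootstrap(m, n_boot=500, seed=1)
        assert out["mean"].iloc[0] == pytest.approx(0.5)
        for v in np.r_[out["ci_low"], out["ci_high"]]:
            assert v in (0.0, 0.5, 1.0)

    def test_single_ecosystem_mean_only(self):
        m = pd.DataFrame([[1.0, 2.0]], columns=[2000, 2001])
        out = mean_trend_with_bootstrap(m, seed=0)
        assert out["ci_low"].isna().all()
        np.testing.assert_allclose(out["mean"], [1.0, 2.0])

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(10, 4)))
        a = mean_trend_with_bootstrap(m, seed=7)
        b = mean_trend_with_bootstrap(m, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_monte_carlo_coverage_near_nominal(self):
        # 20 ecosystems x 5 years of N(0,1); the per-year 95% CI of the
        # cross-ecosystem mean should cover 0 about 95% of the time
        rng = np.random.default_rng(42)
        hits = trials = 0
        for _ in range(60):
            m = pd.DataFrame(rng.normal(size=(20, 5)))
            out = mean_trend_with_bootstrap(m, n_boot=400, seed=rng.integers(2**31))
            hits += int(((out["ci_low"] <= 0) & (0 <= out["ci_high"])).sum())
            trials += len(out)
        coverage = hits / trials
        assert 0.85 <= coverage <= 0.99

    def test_ci_narrows_with_sample_size(self):
        rng = np.random.default_rng(3)
        widths = []
        for n in (10, 40, 160):
            m = pd.DataFrame(rng.normal(size=(n, 3)))
            out = mean_trend_with_bootstrap(m, n_boot=400, seed=5)
            widths.append(float((out["ci_high"] - out["ci_low"]).mean()))
        assert widths[0] > widths[1] > widths[2]
        # O(1/sqrt(n)): quadrupling n roughly halves the width
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.5)


class TestTrendSignificance:
    def test_strict_increase_detected(self):
        s = pd.Series(np.arange(20.0), index=range(1950, 1970))
        tr = trend_significance(s)
        assert tr.slope > 0 and tr.tau_p < 0.05

    def test_constant_series_flat(self):
        s = pd.Series(1.0, index=range(1950, 1970))
        tr = trend_significance(s)
        assert tr.slope == 0.0 and not tr.significant

    def test_white_noise_type_i_error_near_alpha(self):
        rng = np.random.default_rng(8)
        rejections = sum(
            trend_significance(
                pd.Series(rng.normal(size=60), index=range(1950, 2010))
            ).significant
            for _ in range(200)
        )
        assert rejections / 200 <= 0.12

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            trend_significance(pd.Series([1.0] * 5, index=range(5)))


class TestPCA:
    def test_rank_one_matrix_single_component(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([1.0, -1.0, 0.5])
        m = pd.DataFrame(np.outer(u, v))
        res = pca_trajectories(m, scale=False)
        assert res.eigenvalues[0] > 0
        np.testing.assert_allclose(res.eigenvalues[1:], 0, atol=1e-20)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(10, 6)))
        res = pca_trajectories(m)
        S = res.scores.to_numpy()
        G = S.T @ S
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0, atol=1e-8)

    def test_eigenvalues_match_independent_spectral_decomposition(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(size=(10, 6)))
        res = pca_trajectories(m, scale=True)
        X = m.to_numpy()
        Z = (X - X.mean(0)) / X.std(0)
        eig = np.sort(np.linalg.eigvalsh(Z.T @ Z / len(Z)))[::-1]
        np.testing.assert_allclose(res.eigenvalues, eig, atol=1e-10)

    def test_scaled_eigenvalues_sum_to_variable_count(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.normal(size=(12, 7)))
        res = pca_trajectories(m, scale=True)
        assert res.eigenvalues.sum() == pytest.approx(7.0)

    def test_constant_column_dropped_when_scaling(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.normal(size=(8, 3)), columns=["a", "b", "c"])
        m["const"] = 5.0
        res = pca_trajectories(m, scale=True)
        assert res.dropped_columns == ["const"]
        assert res.eigenvalues.sum() == pytest.approx(3.0)

    def test_nan_rejected(self):
        m = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            pca_trajectories(m)


class TestWardClustering:
    def test_separated_blobs_perfectly_recovered(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0.0, 0.1, size=(12, 3))
        b = rng.normal(10.0, 0.1, size=(8, 3))
        scores = pd.DataFrame(np.vstack([a, b]))
        labels = ahc_ward(scores, k=2)
        assert labels.iloc[:12].nunique() == 1
        assert labels.iloc[12:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_k_one_single_cluster(self):
        scores = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 2)))
        assert (ahc_ward(scores, k=1) == 1).all()

    def test_duplicated_rows_share_cluster(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(6, 2))
        scores = pd.DataFrame(np.vstack([base, base[:1]]))
        labels = ahc_ward(scores, k=3)
        assert labels.iloc[0] == labels.iloc[-1]

    def test_k_above_n_rejected(self):
        scores = pd.DataFrame(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            ahc_ward(scores, k=4)

    def test_cluster_trajectories_end_to_end(self):
        rng = np.random.default_rng(10)
        up = 1.0 + 0.01 * np.arange(30) + rng.normal(0, 0.01, size=(7, 30))
        down = 1.0 - 0.01 * np.arange(30) + rng.normal(0, 0.01, size=(5, 30))
        m = pd.DataFrame(np.vstack([up, down]))
        res = cluster_trajectories(m, k=2)
        assert res.labels.iloc[:7].nunique() == 1
        assert res.labels.iloc[7:].nunique() == 1


def _enumerated_tail(N, K, n, k, direction):
    """Exhaustive subset enumeration of the hypergeometric tail."""
    items = [1] * K + [0] * (N - K)
    hits = total = 0
    for combo in itertools.combinations(range(N), n):
        total += 1
        drawn = sum(items[i] for i in combo)
        if direction == "over" and drawn >= k:
            hits += 1
        if direction == "under" and drawn <= k:
            hits += 1
    return hits / total


class TestHypergeometricEnrichment:
    @pytest.mark.parametrize(
        "N,K,n,k",
        [(12, 5, 4, 3), (15, 6, 5, 1), (10, 3, 6, 2), (14, 7, 7, 5)],
    )
    def test_matches_exhaustive_enumeration(self, N, K, n, k):
        p, direction = hypergeom_enrichment(N, K, n, k)
        assert p == pytest.approx(_enumerated_tail(N, K, n, k, direction), rel=1e-12)

    def test_expected_count_not_significant(self):
        # k exactly at expectation: both tails are wide
        N, K, n = 20, 10, 8
        k = round(n * K / N)
        p, _ = hypergeom_enrichment(N, K, n, k)
        assert p > 0.3

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(10, 5, 4, 5)


class TestEnrichmentTable:
    def test_percentages_reconstruct_counts(self):
        labels = pd.Series(
            [1] * 4 + [2] * 6, index=[f"e{i}" for i in range(10)], name="cluster"
        )
        modalities = pd.DataFrame(
            {"hot": [True] * 5 + [False] * 5},
            index=labels.index,
        )
        out = enrich_modalities(labels, modalities)
        row = out[(out.cluster == 1) & (out.modality == "hot")].iloc[0]
        assert row.occ_all == pytest.approx(50.0)  # 5/10
        k = row.occ_cluster / 100 * 4
        assert k == pytest.approx(round(k))  # counts recoverable
        assert row.selected == pytest.approx(100.0 * k / 5)
        assert 0 < row.p_value <= 1

    def test_absent_modality_skipped(self):
        labels = pd.Series([1, 1, 2, 2], index=list("abcd"))
        modalities = pd.DataFrame({"never": [False] * 4}, index=labels.index)
        assert enrich_modalities(labels, modalities).empty


class TestModalityRules:
    def test_trend_threshold_and_type_rules(self, toy_ecosystems):
        years = np.arange(1950, 2011)
        indices = pd.DataFrame(
            {
                "ecosystem_id": "NS",
                "year": years,
                "fib": -0.01 * (years - 1950),
                "mtl": 3.8 + 0.0 * years,
                "total_catch": 100.0 + years - 1950,
                "ppr_pp": 0.05 + 0.0 * years,
                "l_index": np.where(years >= 1990, 0.06, 0.02),
                "ssp_overexploited_collapsed": 0.6,
                "finfish_fraction": 0.9,
            }
        )
        out = apply_modality_rules(indices, toy_ecosystems)
        row = out.loc["NS"]
        assert row["FiB decreasing"]
        assert not row["FiB increasing"]
        assert row["MTL stable"]
        assert row["Catch increase"]
        assert row["High Lindex >0.05 (1990-2010)"]
        assert row["High MTL (>3.60)"]
        assert row["Temperate ecosystems"]
        assert not row["Polar ecosystems"]

    def test_default_rules_cover_table_modalities(self):
        rules = default_modality_rules()
        assert "FiB decreasing" in rules
        assert "Polar ecosystems" in rules
        for rule in rules.values():
            assert rule["kind"] in {
                "trend",
                "mean_gt",
                "mean_lt",
                "mean_between",
                "eco_type",
            }
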