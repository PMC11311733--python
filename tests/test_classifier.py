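import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from coronadx import (
    FeaturePreprocessor,
    MetricTriple,
    PipelineConfig,
    composite_select,
    correlation_filter,
    nested_cv,
    preprocess_features,
    rank_features_wilcoxon,
)
from coronadx.simulate import SimParams, generate_cohort


def naive_correlation_filter(X, ranked, rho, coverage, top_pool=1000):
    """Literal restatement of the redundancy rule, feature by feature."""
    pool = list(ranked)[:top_pool]
    retained = []
    for f in pool:
        excluded = False
        for g in pool:
            if g == f:
                continue
            a, b = X[f].to_numpy(), X[g].to_numpy()
            if a.std() == 0 or b.std() == 0:
                continue
            corr = np.corrcoef(a, b)[0, 1]
            if corr > rho and coverage[g] > coverage[f]:
                excluded = True
                break
        if not excluded:
            retained.append(f)
    return retained


class TestWilcoxonRanking:
    def test_matches_exact_ranksum_oracle(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(0, 1, (8, 6)),
                         columns=[f"f{i}" for i in range(6)])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        ranked = rank_features_wilcoxon(X, y)
        exact_p = {
            c: mannwhitneyu(X[c][y == 1], X[c][y == 0],
                            alternative="two-sided", method="exact").pvalue
            for c in X.columns
        }
        # asymptotic p preserves the exact-p ordering on untied data
        expect = sorted(X.columns, key=lambda c: exact_p[c])
        assert list(ranked["feature"]) == expect

    def test_identical_feature_p_one(self):
        X = pd.DataFrame({"same": np.ones(10), "good": np.r_[np.zeros(5), np.ones(5)]})
        y = np.array([0] * 5 + [1] * 5)
        ranked = rank_features_wilcoxon(X, y).set_index("feature")
        assert ranked.loc["same", "p"] == pytest.approx(1.0)
        assert ranked.index[0] == "good"

    def test_separating_feature_ranked_first(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(0, 1, (20, 5)),
                         columns=[f"f{i}" for i in range(5)])
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        X["sep"] = y * 10.0 + rng.normal(0, 0.01, 20)
        assert rank_features_wilcoxon(X, y)["feature"].iloc[0] == "sep"

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": np.arange(4.0)})
        with pytest.raises(ValueError):
            rank_features_wilcoxon(X, np.ones(4, int))


class TestCorrelationFilter:
    def test_rho_one_retains_all(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(0, 1, (15, 6)),
                         columns=[f"f{i}" for i in range(6)])
        cov = pd.Series(rng.random(6), index=X.columns)
        kept = correlation_filter(X, list(X.columns), 1.0, cov)
        assert kept == list(X.columns)

    def test_duplicate_column_lower_coverage_dropped(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, 20)
        X = pd.DataFrame({"hi": base, "lo": base.copy(),
                          "other": rng.normal(0, 1, 20)})
        cov = pd.Series({"hi": 0.9, "lo": 0.8, "other": 0.7})
        kept = correlation_filter(X, ["lo", "hi", "other"], 0.5, cov)
        assert "hi" in kept and "lo" not in kept and "other" in kept

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, d = 25, int(rng.integers(5, 21))
        base = rng.normal(0, 1, (n, 3))
        X = pd.DataFrame(
            base[:, rng.integers(0, 3, d)] * rng.uniform(0.5, 2, d)
            + rng.normal(0, rng.uniform(0.1, 2), (n, d)),
            columns=[f"f{i:02d}" for i in range(d)],
        )
        cov = pd.Series(rng.random(d), index=X.columns)
        ranked = list(rng.permutation(X.columns))
        rho = float(rng.choice([0.5, 0.6, 0.7, 0.8]))
        assert correlation_filter(X, ranked, rho, cov) == \
            naive_correlation_filter(X, ranked, rho, cov)


class TestCompositeSelect:
    def test_single_config(self):
        assert composite_select({(20, 0.5): MetricTriple(0.6, 0.5, 0.7)}) == (20, 0.5)

    def test_dominant_config_wins(self):
        metrics = {
            (20, 0.5): MetricTriple(0.70, 0.65, 0.72),
            (40, 0.5): MetricTriple(0.60, 0.55, 0.62),
            (20, 0.8): MetricTriple(0.65, 0.60, 0.67),
        }
        assert composite_select(metrics) == (20, 0.5)

    def test_hand_computed_z_sums(self):
        metrics = {
            (20, 0.5): MetricTriple(0.60, 0.70, 0.50),
            (40, 0.5): MetricTriple(0.70, 0.50, 0.60),
            (20, 0.8): MetricTriple(0.50, 0.60, 0.70),
            (40, 0.8): MetricTriple(0.65, 0.65, 0.65),
        }
        keys = sorted(metrics)
        M = np.array([metrics[k].as_array() for k in keys])
        Z = (M - M.mean(0)) / M.std(0)
        expect = keys[int(np.argmax(Z.sum(1)))]
        assert composite_select(metrics) == expect

    def test_tie_breaks_to_smaller_config(self):
        same = MetricTriple(0.6, 0.6, 0.6)
        metrics = {(40, 0.8): same, (20, 0.8): same, (20, 0.5): same}
        assert composite_select(metrics) == (20, 0.5)


class TestPreprocess:
    def test_high_missingness_feature_dropped(self):
        rng = np.random.default_rng(4)
        rows = []
        for s in range(20):
            rows.append({"sample_id": f"s{s:02d}", "np_id": "NP1",
                         "protein_group": "Pgood",
                         "log2_intensity": rng.normal(20, 1)})
            if s < 7:   # 13/20 = 65% missing
                rows.append({"sample_id": f"s{s:02d}", "np_id": "NP1",
                             "protein_group": "Psparse",
                             "log2_intensity": rng.normal(18, 1)})
        quant = pd.DataFrame(rows)
        meta = pd.DataFrame({
            "sample_id": [f"s{s:02d}" for s in range(20)],
            "case_status": [0, 1] * 10,
            "plate_id": ["PL0"] * 10 + ["PL1"] * 10,
        })
        fm = preprocess_features(quant, meta, {"Extracellular": {"Pgood"}})
        assert "Pgood|NP1" in fm.features
        assert "Psparse|NP1" not in fm.features

    def test_psa_window_restricts_subjects(self):
        p = SimParams(n_subjects=60, n_proteins=10, n_differential=0, seed=6)
        quant, meta, ann, _ = generate_cohort(p)
        fm = preprocess_features(quant, meta, ann, psa_window=(4, 10))
        inside = meta[(meta["psa"] >= 4) & (meta["psa"] <= 10)]
        assert set(fm.X.index) == set(inside["sample_id"])

    def test_residuals_centered_within_plates(self):
        # plate effects only: residualization removes the plate means
        p = SimParams(n_subjects=80, n_proteins=12, n_differential=0,
                      plate_sd=1.0, np_sd=0, platenp_sd=0, subject_sd=0,
                      resid_sd=0.3, composition_sd=0,
                      missing_intercept=-np.inf, seed=7)
        quant, meta, ann, _ = generate_cohort(p)
        fm = preprocess_features(quant, meta, ann)
        plates = meta.set_index("sample_id")["plate_id"]
        for col in fm.features[:5]:
            vals = fm.X[col]
            for plate, members in vals.groupby(plates.reindex(vals.index)):
                se = members.std() / np.sqrt(len(members)) + 1e-12
                assert abs(members.mean()) < 3 * se + 0.05

    def test_no_leakage_from_held_out_samples(self):
        p = SimParams(n_subjects=50, n_proteins=15, n_differential=3, seed=8)
        quant, meta, ann, _ = generate_cohort(p)
        train_meta = meta.iloc[:35]
        test_ids = set(meta.iloc[35:]["sample_id"])
        prep1 = FeaturePreprocessor().fit(quant, train_meta, ann)
        corrupted = quant.copy()
        corrupted.loc[corrupted["sample_id"].isin(test_ids),
                      "log2_intensity"] += 100.0
        prep2 = FeaturePreprocessor().fit(corrupted, train_meta, ann)
        f1 = prep1.transform(quant, train_meta)
        f2 = prep2.transform(corrupted, train_meta)
        pd.testing.assert_frame_equal(f1.X, f2.X)
        y = train_meta["case_status"].to_numpy()
        pd.testing.assert_frame_equal(rank_features_wilcoxon(f1.X, y),
                                      rank_features_wilcoxon(f2.X, y))


@pytest.fixture(scope="module")
def cohort():
    p = SimParams(n_subjects=60, n_proteins=25, n_differential=6,
                  effect_size_log2=1.5, seed=9)
    return generate_cohort(p)


class TestNestedCV:
    def _grid(self):
        return [PipelineConfig(m, r, top_pool=60, n_trees=50)
                for m in (10, 20) for r in (0.5, 0.8)]

    def test_every_subject_scored_once_per_config_and_seed(self, cohort):
        quant, meta, ann, _ = cohort
        fp = nested_cv(quant, meta, ann, self._grid(), n_outer=4, n_inner=2,
                       n_seeds=2, base_seed=3, mtry_grid=[2])
        assert fp.scores.shape == (60, 4, 2)
        assert ((fp.scores >= 0) & (fp.scores <= 1)).all()
        for s in range(2):
            assert len(np.unique(fp.fold_ids[:, s])) == 4

    def test_deterministic_under_seed(self, cohort):
        quant, meta, ann, _ = cohort
        grid = self._grid()[:2]
        a = nested_cv(quant, meta, ann, grid, n_outer=3, n_inner=2,
                      n_seeds=1, base_seed=5, mtry_grid=[2])
        b = nested_cv(quant, meta, ann, grid, n_outer=3, n_inner=2,
                      n_seeds=1, base_seed=5, mtry_grid=[2])
        assert np.array_equal(a.scores, b.scores)
        assert np.array_equal(a.fold_ids, b.fold_ids)

    def test_planted_signal_detected(self, cohort):
        quant, meta, ann, _ = cohort
        fp = nested_cv(quant, meta, ann, self._grid(), n_outer=4, n_inner=2,
                       n_seeds=1, base_seed=1, mtry_grid=[3])
        best = max(m.auc for m in fp.pooled_metrics().values())
        assert best > 0.8
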