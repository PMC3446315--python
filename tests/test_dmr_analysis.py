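"""Quantification, CV ranking, enrichment, sample structure, metaprofiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from medipkit import coupling_norm as cn
from medipkit import dmr_analysis as da
from medipkit import synthetic as syn

from conftest import feature_table


def toy_matrix(values, classes=None, samples=None):
    """Build a FeatureMethylationMatrix from a plain array."""
    values = np.asarray(values, dtype=float)
    n_f, n_s = values.shape
    fid = [f"F{i:03d}" for i in range(n_f)]
    sid = samples if samples is not None else [f"s{j}" for j in range(n_s)]
    feats = pd.DataFrame(
        {"feature_class": classes if classes is not None else ["CDS"] * n_f,
         "chrom": "chr1", "start": np.arange(n_f) * 1000,
         "end": np.arange(n_f) * 1000 + 500},
        index=pd.Index(fid, name="feature"),
    )
    meta = pd.DataFrame(
        {"individual_id": [s.split("_")[-1] if "_" in s else "ind1" for s in sid],
         "tissue": [s.split("_")[0] for s in sid],
         "tissue_group": [s.split("_")[0].rstrip("0123456789") for s in sid]},
        index=pd.Index(sid, name="sample_id"),
    )
    return da.FeatureMethylationMatrix(
        values=pd.DataFrame(values, index=feats.index, columns=sid),
        features=feats, samples=meta,
    )


class TestQuantify:
    def test_rpkm_worked_example(self):
        feats = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000],
                              "name": ["f1"]})
        starts = np.arange(10) * 50
        reads = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 40})
        out = da.quantify_reads({"s1": reads}, feats, totals={"s1": 1_000_000})
        assert out.loc["f1", "s1"] == pytest.approx(10.0)

    def test_no_reads_gives_zero(self):
        feats = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000],
                              "name": ["f1"]})
        reads = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [50]})
        out = da.quantify_reads({"s1": reads}, feats, totals={"s1": 100})
        assert out.loc["f1", "s1"] == 0

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        feats = pd.DataFrame({"chrom": "chr1", "start": [0, 2000, 5000],
                              "end": [1000, 4000, 9000], "name": ["a", "b", "c"]})
        starts = rng.integers(0, 9000, 500)
        reads = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 50})
        v1 = da.quantify_reads({"s": reads}, feats, totals={"s": 500})
        doubled = pd.concat([reads, reads], ignore_index=True)
        v2 = da.quantify_reads({"s": doubled}, feats, totals={"s": 1000})
        pd.testing.assert_frame_equal(v1, v2)

    def test_zero_length_feature_rejected(self):
        feats = pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [10],
                              "name": ["f1"]})
        with pytest.raises(ValueError, match="zero-length"):
            da.quantify_reads({"s1": pd.DataFrame(columns=["chrom", "start", "end"])},
                              feats, totals={"s1": 1})

    def test_mean_rms_over_overlapping_bins(self):
        grid = cn.make_bins({"chr1": 2000}, 500, 250)
        feats = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [600],
                              "name": ["f1"]})
        vals = np.zeros((grid.n_bins, 1))
        vals[:3, 0] = [0.2, 0.4, 0.9]  # bins [0,500),[250,750),[500,1000) overlap
        out = da.quantify_bins(vals, grid, feats, ["s1"], mode="mean_rms")
        assert out.loc["f1", "s1"] == pytest.approx(np.mean([0.2, 0.4, 0.9]))


class TestCvRank:
    def test_identical_profiles_cv_zero(self):
        m = toy_matrix(np.full((5, 6), 0.4),
                       samples=[f"{t}_ind{i}" for t in ("cortex", "cerebellum", "blood")
                                for i in (1, 2)])
        rec = da.cv_rank(m)
        np.testing.assert_allclose(rec["cv"], 0.0, atol=1e-12)

    def test_hand_computed_group_means(self):
        # group means {0, 2, 4}: mean 2, SD (n-1) = 2, CV = 2/3
        m = toy_matrix(np.array([[0.0, 2.0, 4.0]]),
                       samples=["cortex_ind1", "cerebellum_ind1", "blood_ind1"])
        rec = da.cv_rank(m)
        assert rec["cv"].iloc[0] == pytest.approx(2.0 / 3.0)

    def test_constant_shift_decreases_cv(self):
        base = np.array([[0.0, 2.0, 4.0]])
        samples = ["cortex_ind1", "cerebellum_ind1", "blood_ind1"]
        cvs = [da.cv_rank(toy_matrix(base + c, samples=samples))["cv"].iloc[0]
               for c in (0, 1, 5, 10)]
        assert all(a > b for a, b in zip(cvs, cvs[1:]))

    def test_ranks_are_permutation_with_id_tiebreak(self):
        vals = np.array([[0.1, 0.1, 0.5], [0.1, 0.1, 0.5], [0.2, 0.2, 0.2]])
        m = toy_matrix(vals, samples=["cortex_ind1", "cerebellum_ind1", "blood_ind1"])
        rec = da.cv_rank(m)
        assert sorted(rec["rank"]) == [1, 2, 3]
        tied = rec[rec["cv"] == rec["cv"].max()]
        assert tied["feature"].tolist() == sorted(tied["feature"])

    def test_sample_mode(self):
        vals = np.random.default_rng(1).random((10, 6))
        m = toy_matrix(vals, samples=[f"cortex{k}_ind1" for k in range(6)])
        rec = da.cv_rank(m, group_by="sample")
        expect = vals.std(axis=1, ddof=1) / (vals.mean(axis=1) + 1)
        got = rec.set_index("feature")["cv"]
        np.testing.assert_allclose(got[[f"F{i:03d}" for i in range(10)]], expect)

    def test_single_group_rejected(self):
        m = toy_matrix(np.random.default_rng(0).random((4, 2)),
                       samples=["blood_ind1", "blood_ind2"])
        with pytest.raises(ValueError, match="2 groups"):
            da.cv_rank(m)


class TestSelectDmrs:
    def records(self, cvs):
        rec = pd.DataFrame({"feature": [f"F{i}" for i in range(len(cvs))],
                            "feature_class": "CDS", "cv": cvs})
        rec = rec.sort_values(["cv", "feature"], ascending=[False, True])
        rec["rank"] = np.arange(1, len(rec) + 1)
        return rec

    def test_top_k_ordering(self):
        sel = da.select_dmrs(self.records([0.9, 1.2, 0.1, 2.0]), top_k=3)
        assert sel["cv"].tolist() == [2.0, 1.2, 0.9]

    def test_k_equals_n_is_identity(self):
        rec = self.records([0.5, 0.7])
        assert len(da.select_dmrs(rec, top_k=2)) == 2

    def test_threshold_above_max_is_empty(self):
        assert len(da.select_dmrs(self.records([0.5, 0.7]), cv_gt=0.9)) == 0

    def test_k_exceeding_n_returns_all(self):
        assert len(da.select_dmrs(self.records([0.5]), top_k=10)) == 1

    def test_exactly_one_mode(self):
        with pytest.raises(ValueError):
            da.select_dmrs(self.records([0.5]), top_k=1, cv_gt=0.1)


class TestEnrichment:
    def test_hand_computed_chi_square(self):
        feats = feature_table(100, classes=("A", "B")).set_index("name")
        feats = feats.rename(columns={})
        dmr = pd.DataFrame({"feature": [f"F{i:05d}" for i in range(40)],
                            "feature_class": ["A"] * 30 + ["B"] * 10})
        res = da.enrichment_oe(dmr, feats)
        res = res.set_index("feature_class")
        assert res.loc["A", "oe"] == pytest.approx(1.5)
        assert res.loc["B", "oe"] == pytest.approx(0.5)
        assert res["chi2"].iloc[0] == pytest.approx(10.0)
        assert res["df"].iloc[0] == 1
        assert res["p_value"].iloc[0] == pytest.approx(stats.chi2.sf(10, 1))

    def test_proportional_sampling_gives_unit_oe(self):
        feats = feature_table(200, classes=("A", "A", "B", "B")).set_index("name")
        dmr = pd.DataFrame({"feature": [f"F{i:05d}" for i in range(0, 200, 2)]})
        dmr["feature_class"] = feats.loc[dmr["feature"], "feature_class"].to_numpy()
        res = da.enrichment_oe(dmr, feats)
        assert np.allclose(res["oe"], 1.0)
        assert res["chi2"].iloc[0] == pytest.approx(0.0)

    def test_observed_and_expected_sum_to_dmr_count(self):
        feats = feature_table(300).set_index("name")
        rng = np.random.default_rng(0)
        pick = rng.choice(feats.index, 60, replace=False)
        dmr = pd.DataFrame({"feature": pick,
                            "feature_class": feats.loc[pick, "feature_class"].to_numpy()})
        res = da.enrichment_oe(dmr, feats)
        assert res["observed"].sum() == 60
        assert res["expected"].sum() == pytest.approx(60)

    def test_sparse_class_pooled(self, caplog):
        feats = feature_table(201, classes=("A", "B")).set_index("name")
        feats.iloc[-1, feats.columns.get_loc("feature_class")] = "RARE"
        dmr = pd.DataFrame({"feature": [f"F{i:05d}" for i in range(10)],
                            "feature_class": ["A", "B"] * 5})
        res = da.enrichment_oe(dmr, feats)
        assert "other" in set(res["feature_class"])
        assert "RARE" not in set(res["feature_class"])


class TestSampleStructure:
    def test_self_correlation_unit_diagonal(self):
        m = toy_matrix(np.random.default_rng(0).random((20, 4)))
        corr = da.sample_correlation(m)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr, corr.T)

    def test_affine_samples_fully_correlated(self):
        m = toy_matrix(np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]]))
        assert da.sample_correlation(m).iloc[0, 1] == pytest.approx(1.0)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.random((20, 5))
        corr = da.sample_correlation(toy_matrix(X)).to_numpy()
        for i in range(5):
            for j in range(5):
                x, y = X[:, i], X[:, j]
                manual = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
                assert abs(corr[i, j] - manual) < 1e-12

    def test_zero_variance_sample_named(self):
        vals = np.random.default_rng(0).random((10, 3))
        vals[:, 1] = 0.5
        with pytest.raises(ValueError, match="s1"):
            da.sample_correlation(toy_matrix(vals))

    def test_identical_samples_merge_at_zero(self):
        vals = np.random.default_rng(0).random((30, 3))
        vals[:, 1] = vals[:, 0]
        corr = da.sample_correlation(toy_matrix(vals))
        link, _ = da.cluster_samples(corr)
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_correlated_pair_merges_first(self):
        t = np.linspace(0, 1, 50)
        vals = np.stack([t, t + 0.01 * np.sin(9 * t), 1 - t], axis=1)
        corr = da.sample_correlation(toy_matrix(vals))
        link, _ = da.cluster_samples(corr)
        assert sorted(link[0, :2].astype(int)) == [0, 1]

    def test_nan_rejected(self):
        corr = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        corr.iloc[0, 1] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            da.cluster_samples(corr)


class TestPca:
    def test_duplicated_sample_same_scores(self):
        vals = np.random.default_rng(2).random((50, 4))
        vals[:, 3] = vals[:, 0]
        scores, _ = da.pca_samples(toy_matrix(vals), n_components=2)
        np.testing.assert_allclose(scores.iloc[0], scores.iloc[3], atol=1e-10)

    def test_variances_non_increasing(self):
        scores, var = da.pca_samples(
            toy_matrix(np.random.default_rng(3).random((100, 10))), n_components=5)
        assert (np.diff(var) <= 1e-12).all()

    def test_reconstruction_error_decreases_with_k(self):
        rng = np.random.default_rng(4)
        X = rng.random((10, 100))  # samples x features
        Xc = X - X.mean(axis=0)
        errs = []
        for k in range(1, 8):
            U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
            recon = U[:, :k] @ np.diag(S[:k]) @ Vt[:k]
            errs.append(((Xc - recon) ** 2).sum())
        m = toy_matrix(X.T)
        scores, var = da.pca_samples(m, n_components=7)
        assert all(a >= b for a, b in zip(errs, errs[1:]))
        # component variances from our PCA match the SVD spectrum
        np.testing.assert_allclose(var, S[:7] ** 2 / (10 - 1), rtol=1e-8)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            da.pca_samples(toy_matrix(np.full((10, 4), 0.3)), n_components=2)


class TestIndividualDifferences:
    def sim_matrix(self, seed=0, rho=0.7, n_feat=800):
        feats = feature_table(n_feat)
        cfg = syn.SimulationConfig(seed=seed, rho_individual=rho,
                                   dmr_fraction={"default": 0.05})
        meth = syn.simulate_methylome(feats, cfg)
        return syn.methylome_matrix(meth, feats, cfg)

    def test_same_individual_zero_difference(self):
        m = self.sim_matrix()
        diff, _ = da.individual_differences(m, "ind1", "ind1", n_permutations=10)
        assert np.allclose(diff.to_numpy(), 0.0)

    def test_swap_antisymmetry(self):
        m = self.sim_matrix()
        d1, c1 = da.individual_differences(m, "ind1", "ind2", n_permutations=50, seed=3)
        d2, c2 = da.individual_differences(m, "ind2", "ind1", n_permutations=50, seed=3)
        np.testing.assert_allclose(d1.to_numpy(), -d2.to_numpy())
        np.testing.assert_allclose(c1["r"], c2["r"])

    def test_missing_individual_rejected(self):
        m = self.sim_matrix()
        with pytest.raises(ValueError, match="missing"):
            da.individual_differences(m, "ind1", "nobody", n_permutations=10)

    def test_cortex_regions_averaged(self):
        feats = feature_table(200)
        cfg = syn.SimulationConfig(seed=1, cortex_regions=3)
        meth = syn.simulate_methylome(feats, cfg)
        m = syn.methylome_matrix(meth, feats, cfg)
        diff, cors = da.individual_differences(m, "ind1", "ind2", n_permutations=20)
        assert set(diff.columns) == {"blood", "cerebellum", "cortex"}

    def test_variability_summary_antisymmetric_invariant(self):
        m = self.sim_matrix()
        d1, _ = da.individual_differences(m, "ind1", "ind2", n_permutations=5)
        v = da.variability_by_class(d1, m.features)
        assert (v.to_numpy() >= 0).all()
        assert set(v.index) <= set(m.features["feature_class"])


class TestMetagene:
    def grid_with(self, L=20_000, values=None):
        grid = cn.make_bins({"chr1": L}, 500, 250)
        scores = np.full(grid.n_bins, 0.5) if values is None else values
        return grid, scores

    def genes(self, *rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                           "gene_id", "utr3_len"])

    def test_constant_signal_flat_profile(self):
        grid, scores = self.grid_with()
        profile, used, skipped = da.metagene_profile(
            scores, grid, self.genes(("chr1", 5000, 15000, "+", "g", 500)))
        assert used == 1 and skipped == 0
        np.testing.assert_allclose(profile, 0.5)

    def test_step_function_reproduced_at_scaled_boundary(self):
        grid, scores = self.grid_with()
        # signal 0 left of 10,000 and 1 right of it; gene body [5000, 15000)
        mid = (grid.starts + grid.ends) // 2
        scores = (mid >= 10_000).astype(float)
        scores[(grid.starts < 10_000) & (grid.ends > 10_000)] = np.nan  # boundary bins out
        profile, _, _ = da.metagene_profile(
            scores, grid, self.genes(("chr1", 5000, 15000, "+", "g", 500)),
            n_body_bins=10, flank=2000, n_flank_bins=4)
        body = profile[4:14]
        assert np.nanmax(body[:4]) <= 0.2 and np.nanmin(body[6:]) >= 0.8

    def test_minus_strand_mirrors_plus(self):
        grid, _ = self.grid_with()
        mid = (grid.starts + grid.ends) // 2
        scores = np.interp(mid, [0, 20_000], [0.0, 1.0])
        plus, _, _ = da.metagene_profile(
            scores, grid, self.genes(("chr1", 5000, 15000, "+", "g", 500)),
            n_body_bins=10, flank=2000, n_flank_bins=4)
        minus, _, _ = da.metagene_profile(
            scores, grid, self.genes(("chr1", 5000, 15000, "-", "g", 500)),
            n_body_bins=10, flank=2000, n_flank_bins=4)
        np.testing.assert_allclose(minus, plus[::-1], atol=1e-9)

    def test_short_gene_skipped(self):
        grid, scores = self.grid_with()
        profile, used, skipped = da.metagene_profile(
            scores, grid, self.genes(("chr1", 100, 120, "+", "tiny", 0)),
            n_body_bins=40)
        assert used == 0 and skipped == 1
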