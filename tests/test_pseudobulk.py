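"""Pseudo-bulk aggregation, NB Wald DE, hurdle test, cluster merging and
marker classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from regulome import pseudobulk as pb
from regulome.simulate import SimulationConfig, generate_multiome

from conftest import toy_cells


class TestFilterGenes:
    def test_boundary_gene_retained(self):
        # count 2 in exactly 5 cells: satisfies ">1 count in >=5 nuclei"
        X = np.zeros((10, 2), dtype=int)
        X[:5, 0] = 2
        cells = toy_cells(X, cluster=["a"] * 10)
        out = pb.filter_genes(cells)
        assert list(out.var_names) == ["g0"]

    def test_all_zero_gene_removed(self):
        X = np.zeros((6, 1), dtype=int)
        cells = toy_cells(X, cluster=["a"] * 6)
        assert pb.filter_genes(cells).n_vars == 0

    def test_predicted_gene_ids_removed(self):
        X = np.full((6, 3), 5, dtype=int)
        cells = toy_cells(X, cluster=["a"] * 6)
        cells.var_names = ["Nfix", "Gm12345", "0610009B22Rik"]
        out = pb.filter_genes(cells)
        assert list(out.var_names) == ["Nfix"]

    def test_survivors_match_brute_force_predicate(self, rng):
        X = rng.integers(0, 4, (50, 100))
        cells = toy_cells(X, cluster=["a"] * 50)
        out = pb.filter_genes(cells)
        keep = [(X[:, j] >= 2).sum() >= 5 for j in range(100)]
        assert out.n_vars == sum(keep)


def _clustered_cells(rng, n_per_rep=(30, 25, 40), genes=20):
    rows, labels, reps = [], [], []
    for i, n in enumerate(n_per_rep):
        rows.append(rng.integers(0, 8, (n, genes)))
        labels += ["c0"] * n
        reps += [f"r{i}"] * n
    X = np.vstack(rows)
    return toy_cells(X, cluster=labels, replicate=reps,
                     sex=["F" if r != "r2" else "M" for r in reps])


class TestAggregate:
    def test_replicate_at_threshold_excluded(self, rng):
        cells = _clustered_cells(rng, n_per_rep=(20, 30, 40))
        out = pb.aggregate(cells, "c0", min_cells=20)
        assert out.excluded == ["r0"]
        assert list(out.counts.columns) == ["r1", "r2"]

    def test_sum_conservation_over_retained_cells(self, rng):
        cells = _clustered_cells(rng)
        out = pb.aggregate(cells, "c0", min_cells=20)
        X = np.asarray(cells.X)
        expected = X[np.isin(cells.obs["replicate"], out.counts.columns)].sum()
        assert out.counts.to_numpy().sum() == expected

    def test_single_cell_replicate_column_equals_cell(self, rng):
        cells = _clustered_cells(rng, n_per_rep=(30, 1))
        out = pb.aggregate(cells, "c0", min_cells=0)
        one = cells[cells.obs["replicate"] == "r1"]
        np.testing.assert_array_equal(out.counts["r1"].to_numpy(),
                                      np.asarray(one.X).ravel())

    def test_unknown_cluster_rejected(self, rng):
        cells = _clustered_cells(rng)
        with pytest.raises(KeyError):
            pb.aggregate(cells, "missing")


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame(np.tile([[10], [20], [30]], (1, 4)))
        np.testing.assert_allclose(pb.size_factors(counts), np.ones(4))

    def test_scaled_column_scale_equivariance(self):
        base = np.array([[10, 10], [40, 40], [90, 90]], dtype=float)
        base[:, 1] *= 2
        f = pb.size_factors(pd.DataFrame(base))
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_matches_direct_formula(self, rng):
        counts = rng.integers(1, 200, (5, 4)).astype(float)
        logs = np.log(counts)
        ratios = np.exp(logs - logs.mean(axis=1, keepdims=True))
        expected = np.median(ratios, axis=0)
        expected /= np.exp(np.mean(np.log(expected)))
        np.testing.assert_allclose(pb.size_factors(pd.DataFrame(counts)),
                                   expected)

    def test_matches_pydeseq2_up_to_normalisation(self, rng):
        from pydeseq2.preprocessing import deseq2_norm
        counts = rng.integers(1, 500, (30, 6)).astype(float)
        _, sf = deseq2_norm(pd.DataFrame(counts).T)
        ours = pb.size_factors(pd.DataFrame(counts))
        ref = np.asarray(sf).ravel()
        np.testing.assert_allclose(ours, ref / np.exp(np.mean(np.log(ref))),
                                   rtol=1e-6)

    def test_no_allnonzero_gene_is_error(self):
        counts = pd.DataFrame([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="pseudo-reference"):
            pb.size_factors(counts)


def _pb_matrix(rng, n_genes=300, n_per_group=4, mean=500.0, disp=0.05,
               lfc_genes=(), down_genes=(), lfc=1.0):
    """NB pseudobulk with ``lfc_genes`` up and ``down_genes`` down in males.

    Balanced planting keeps median-of-ratios size factors anchored on
    null genes (one-directional planting shifts them, as it would in any
    median-of-ratios pipeline)."""
    mu = np.full(n_genes, mean)
    cols = {}
    meta = []
    for g, sex in (("F", "F"), ("M", "M")):
        for r in range(n_per_group):
            m = mu.copy()
            if sex == "M":
                if len(lfc_genes):
                    m[list(lfc_genes)] *= 2.0 ** lfc
                if len(down_genes):
                    m[list(down_genes)] /= 2.0 ** lfc
            lam = rng.gamma(1 / disp, disp, n_genes) * m
            cols[f"{sex}{r}"] = rng.poisson(lam)
            meta.append({"replicate": f"{sex}{r}", "sex": sex, "n_cells": 100})
    return pb.PseudobulkMatrix(
        counts=pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)]),
        meta=pd.DataFrame(meta).set_index("replicate"))


class TestNBWald:
    def test_planted_two_fold_change_recovered(self, rng):
        # balanced up/down planting keeps size factors on the null genes
        mat = _pb_matrix(rng, n_genes=500, lfc_genes=range(50),
                         down_genes=range(50, 100), lfc=1.0)
        res = pb.nb_wald(mat, group_key="sex")
        assert abs(np.median(res["log2FC"][:50]) - 1.0) < 0.1
        assert abs(np.median(res["log2FC"][50:100]) + 1.0) < 0.1

    def test_null_log2fc_near_zero_high_counts(self, rng):
        mat = _pb_matrix(rng, n_genes=400, mean=2000.0)
        res = pb.nb_wald(mat, group_key="sex")
        assert abs(np.median(res["log2FC"])) < 0.05

    def test_type_one_error_within_binomial_ci(self, rng):
        mat = _pb_matrix(rng, n_genes=2000)
        res = pb.nb_wald(mat, group_key="sex")
        rate = (res["p"] < 0.05).mean()
        assert abs(rate - 0.05) < 2.58 * np.sqrt(0.05 * 0.95 / 2000) + 0.005

    def test_confounded_design_rejected(self, rng):
        mat = _pb_matrix(rng, n_genes=20)
        mat.meta["batch"] = np.where(mat.meta["sex"] == "F", "b1", "b2")
        with pytest.raises(ValueError, match="confounded"):
            pb.nb_wald(mat, group_key="sex", covariates=("batch",))

    def test_batch_covariate_supported(self, rng):
        mat = _pb_matrix(rng, n_genes=50)
        mat.meta["batch"] = ["b1", "b2"] * 4
        res = pb.nb_wald(mat, group_key="sex", covariates=("batch",))
        assert res["p"].notna().all()


class TestMarkerLfcTest:
    def test_boundary_log2fc_gives_half_p(self, rng):
        # true log2FC exactly at the threshold: p ~ 0.5 at large counts
        mat = _pb_matrix(rng, n_genes=400, mean=5000.0, lfc_genes=range(20),
                         down_genes=range(20, 40), lfc=2.0)
        mat.meta["cluster_id"] = np.where(mat.meta["sex"] == "M", "focal", "rest")
        res = pb.marker_lfc_test(mat, "focal", lfc_threshold=2.0)
        assert abs(np.median(res["p"][:20]) - 0.5) < 0.2

    def test_strong_marker_significant_null_gene_not(self, rng):
        mat = _pb_matrix(rng, n_genes=300, lfc_genes=range(50), lfc=4.0)
        mat.meta["cluster_id"] = np.where(mat.meta["sex"] == "M", "focal", "rest")
        res = pb.marker_lfc_test(mat, "focal", lfc_threshold=2.0)
        assert (res["p"][:50] < 0.01).mean() > 0.9
        assert np.median(res["p"][50:]) > 0.9


class TestHurdle:
    def _cells(self, rng, n=200, genes=300, shift_genes=(), shift=2.0):
        sex = np.array(["F", "M"])[rng.integers(0, 2, n)]
        base = rng.lognormal(0, 0.5, genes) * 0.5
        mean = np.tile(base, (n, 1))
        if len(shift_genes):
            mean[sex == "M"][:, list(shift_genes)] *= shift  # noqa: copy
            mean[:, list(shift_genes)] *= np.where(sex == "M", shift, 1)[:, None]
        X = rng.poisson(mean)
        cells = toy_cells(X, sex=sex, cluster=["c"] * n)
        cells.obs["total_counts"] = X.sum(axis=1)
        cells.obs["n_genes"] = (X > 0).sum(axis=1)
        return cells

    def test_undetected_gene_excluded(self, rng):
        cells = self._cells(rng)
        X = np.asarray(cells.X)
        X[:, 0] = 0
        cells.X = X
        res = pb.hurdle_test(cells, group_key="sex")
        assert np.isnan(res["p"].iloc[0])

    def test_low_detection_below_min_pct_excluded(self, rng):
        # 4% detection in both groups with min_pct=0.05 -> not tested
        cells = self._cells(rng, n=200)
        X = np.asarray(cells.X)
        X[:, 1] = 0
        for grp in ("F", "M"):  # exactly 4% detection per group
            idx = np.flatnonzero(cells.obs["sex"] == grp)
            X[idx[: max(1, int(0.04 * len(idx)))], 1] = 5
        cells.X = X
        res = pb.hurdle_test(cells, group_key="sex", min_pct=0.05,
                             logfc_threshold=0.0)
        assert np.isnan(res["p"].iloc[1])

    def test_null_statistic_calibrated(self, rng):
        cells = self._cells(rng, n=300, genes=1000)
        res = pb.hurdle_test(cells, group_key="sex", min_pct=0.05,
                             logfc_threshold=0.0)
        p = res["p"].dropna()
        assert sps.kstest(p, "uniform").pvalue > 0.01

    def test_constant_covariate_dropped_with_warning(self, rng):
        cells = self._cells(rng, n=100, genes=30)
        cells.obs["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            pb.hurdle_test(cells, group_key="sex", covariates=("flat",),
                           logfc_threshold=0.0)


class TestMergeAndClassify:
    def test_same_program_clusters_merge(self, rng):
        X = rng.poisson(2.0, (200, 100))
        cells = toy_cells(X, cluster=["a"] * 100 + ["b"] * 100,
                          sex=["F"] * 200)
        merged = pb.merge_clusters(cells, cluster_key="cluster")
        assert merged.nunique() == 1

    def test_distinct_marker_clusters_not_merged(self, rng):
        # markers must be near-absent in the negative cluster to pass the
        # <10%-negative / >25%-positive detection gates
        X = rng.poisson(1.0, (200, 100)).astype(float)
        X[:, :50] = rng.poisson(0.02, (200, 50))
        X[:100, :25] = rng.poisson(6.0, (100, 25))    # 25 markers of a
        X[100:, 25:50] = rng.poisson(6.0, (100, 25))  # 25 markers of b
        cells = toy_cells(X.astype(int), cluster=["a"] * 100 + ["b"] * 100,
                          sex=["F"] * 200)
        merged = pb.merge_clusters(cells, cluster_key="cluster")
        assert merged.nunique() == 2

    def test_marker_fraction_threshold_is_inclusive(self):
        # cluster positive iff >= 25% of nuclei carry >= 1 marker count
        X = np.zeros((2000, 1), dtype=int)
        X[:250, 0] = 1        # exactly 25.0% of the first 1000 cells
        X[1000:1249, 0] = 1   # 24.9% of the second 1000
        cells = toy_cells(X, cluster=["hi"] * 1000 + ["lo"] * 1000)
        cells.var_names = ["Esr1"]
        calls = pb.classify_marker_clusters(cells, "Esr1", threshold_pct=0.25)
        assert bool(calls["hi"]) and not bool(calls["lo"])

    def test_zero_expression_is_negative(self):
        X = np.zeros((100, 1), dtype=int)
        cells = toy_cells(X, cluster=["a"] * 100)
        cells.var_names = ["Esr1"]
        assert not pb.classify_marker_clusters(cells, "Esr1")["a"]

    def test_missing_marker_rejected(self, rng):
        cells = toy_cells(np.ones((10, 2), dtype=int), cluster=["a"] * 10)
        with pytest.raises(KeyError):
            pb.classify_marker_clusters(cells, "Esr1")

    def test_merge_is_idempotent(self, rng):
        X = rng.poisson(1.0, (200, 100)).astype(float)
        X[:100, :25] += rng.poisson(6.0, (100, 25))
        X[100:, 25:50] += rng.poisson(6.0, (100, 25))
        cells = toy_cells(X.astype(int), cluster=["a"] * 100 + ["b"] * 100,
                          sex=["F"] * 200)
        once = pb.merge_clusters(cells, cluster_key="cluster")
        cells.obs["cluster"] = once
        twice = pb.merge_clusters(cells, cluster_key="cluster")
        assert (once == twice).all()
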