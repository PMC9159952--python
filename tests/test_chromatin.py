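"""CPM, multi-condition differential accessibility, chromatin-state
clustering and the maintenance-overlap statistic."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from regulome import chromatin as chrom
from regulome.simulate import (
    NEONATAL_ARCHETYPES, NEONATAL_ARCHETYPE_SIZES, SimulationConfig,
    generate_condition_atac, neonatal_three_group_groups,
)


class TestCPM:
    def test_column_of_total_1e6_unchanged(self):
        counts = pd.DataFrame({"s1": [250_000, 750_000]})
        np.testing.assert_allclose(chrom.cpm(counts)["s1"], [250_000, 750_000])

    def test_doubling_library_halves_cpm_per_count(self, rng):
        counts = pd.DataFrame({"s1": rng.integers(1, 100, 50)})
        doubled = counts * 2
        np.testing.assert_allclose(chrom.cpm(doubled), chrom.cpm(counts))

    def test_columns_sum_to_one_million(self, rng):
        counts = pd.DataFrame(rng.integers(0, 50, (100, 6)) + 1)
        np.testing.assert_allclose(chrom.cpm(counts).sum(axis=0), 1e6)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            chrom.cpm(pd.DataFrame({"s1": [0, 0]}))


def bulk_instance(seed=0, **cfg_over):
    cfg = SimulationConfig(seed=seed, n_peaks=cfg_over.pop("n_peaks", 1200),
                           **cfg_over)
    return generate_condition_atac(cfg)


class TestMultiConditionTest:
    def test_planted_male_specific_closing_detected_pairwise(self):
        counts, design, peaks, truth = bulk_instance(seed=4)
        res = chrom.multi_condition_test(
            counts, design, factors=("sex", "treatment"), contrast="interaction")
        male_open = truth.peak_archetypes == "male-intact-open"
        hits = (res["p_adj"] < 0.05) & male_open.to_numpy()
        # sex x treatment interaction is exactly the male-intact-open pattern
        assert hits.sum() / male_open.sum() > 0.8

    def test_pairwise_contrast_thresholds(self):
        counts, design, peaks, truth = bulk_instance(seed=5)
        intact = design.index[design["treatment"] == "intact"]
        res = chrom.multi_condition_test(
            counts[intact], design.loc[intact], factors=("sex",),
            contrast="sex")
        lfc_col = [c for c in res.columns if c.startswith("log2FC")][0]
        sig = (res["p_adj"] < 0.05) & (res[lfc_col].abs() > 1)
        male_open = (truth.peak_archetypes == "male-intact-open").to_numpy()
        assert (sig & male_open).sum() / male_open.sum() > 0.8
        null = (truth.peak_archetypes == "null").to_numpy()
        assert (sig & null).mean() < 0.01

    def test_pure_interaction_leaves_marginals_null(self, rng):
        # build a 2x2 interaction-only pattern directly
        groups = ["A.ctrl", "A.trt", "B.ctrl", "B.trt"]
        mult = {"A.ctrl": 1, "A.trt": 3, "B.ctrl": 3, "B.trt": 1}
        rows, meta = {}, []
        base = rng.lognormal(np.log(100), 0.5, 500)
        disp = 0.05
        planted = np.arange(50)  # subset, so library offsets stay anchored
        for g in groups:
            sex, trt = g.split(".")
            for r in range(3):
                m = base.copy()
                m[planted] *= mult[g]
                lam = rng.gamma(1 / disp, disp, 500) * m
                rows[f"{g}_{r}"] = rng.poisson(lam)
                meta.append({"sample": f"{g}_{r}", "sex": sex,
                             "treatment": trt})
        counts = pd.DataFrame(rows)
        design = pd.DataFrame(meta).set_index("sample")
        inter = chrom.multi_condition_test(
            counts, design, factors=("sex", "treatment"),
            contrast="interaction")
        assert (inter["p_adj"][:50] < 0.05).mean() > 0.9
        # marginal (main-effect) contrasts stay null on planted peaks
        for factor in ("sex", "treatment"):
            marg = chrom.multi_condition_test(
                counts, design, factors=("sex", "treatment"), contrast=factor)
            assert (marg["p_adj"][:50] < 0.05).mean() < 0.1

    def test_singular_design_rejected(self, rng):
        counts = pd.DataFrame(rng.integers(1, 50, (20, 4)))
        design = pd.DataFrame({"sex": ["F", "F", "M", "M"],
                               "treatment": ["a", "a", "b", "b"]},
                              index=counts.columns)
        with pytest.raises(ValueError):
            chrom.multi_condition_test(counts, design,
                                       factors=("sex", "treatment"),
                                       contrast="interaction")

    def test_single_replicate_group_rejected(self, rng):
        counts = pd.DataFrame(rng.integers(1, 50, (20, 3)))
        design = pd.DataFrame({"sex": ["F", "M", "M"]}, index=counts.columns)
        with pytest.raises(ValueError, match="replicates"):
            chrom.multi_condition_test(counts, design, factors=("sex",),
                                       contrast="sex")


class TestKMeansStates:
    def test_planted_archetypes_recovered_with_high_ari(self):
        counts, design, peaks, truth = bulk_instance(seed=6)
        grp = chrom.cpm(counts).T.groupby(design["group"]).mean().T
        planted = truth.peak_archetypes != "null"
        states = chrom.kmeans_states(grp[planted.to_numpy()], k=4, seed=0)
        keep = states.labels != -1
        ari = adjusted_rand_score(truth.peak_archetypes[planted][keep],
                                  states.labels[keep])
        assert ari > 0.9

    def test_k_one_prunes_anticorrelated_rows(self, rng):
        base = np.tile([1.0, 2.0, 3.0, 4.0], (50, 1))
        base += rng.normal(0, 0.1, base.shape)
        base[0] = [4.0, 3.0, 2.0, 1.0]  # anti-correlated outlier
        mat = pd.DataFrame(base, columns=list("abcd"))
        states = chrom.kmeans_states(mat, k=1, prune_r=0.8, seed=0)
        assert states.labels.iloc[0] == -1
        assert (states.labels.iloc[1:] == 0).all()

    def test_centroids_equal_means_of_retained_members(self, rng):
        counts, design, peaks, truth = bulk_instance(seed=8)
        grp = chrom.cpm(counts).T.groupby(design["group"]).mean().T
        states = chrom.kmeans_states(grp, k=3, seed=1)
        Z = chrom.zscale_rows(grp)
        for c in range(3):
            members = Z[(states.labels == c).reindex(Z.index, fill_value=False)]
            if len(members):
                np.testing.assert_allclose(states.centroids.loc[c],
                                           members.mean(axis=0), atol=1e-9)

    def test_deterministic_under_seed(self, rng):
        mat = pd.DataFrame(rng.normal(size=(200, 4)))
        a = chrom.kmeans_states(mat, k=3, seed=5)
        b = chrom.kmeans_states(mat, k=3, seed=5)
        assert (a.labels == b.labels).all()

    def test_k_larger_than_rows_rejected(self, rng):
        mat = pd.DataFrame(rng.normal(size=(3, 4)))
        with pytest.raises(ValueError):
            chrom.kmeans_states(mat, k=10)


class TestNEStates:
    def _clean_patterns(self, rng, n_open=60, n_close=40, noise=0.05):
        rows = []
        for _ in range(n_open):
            rows.append([1.0, 4.0, 4.0] + rng.normal(0, noise, 3))
        for _ in range(n_close):
            rows.append([4.0, 1.0, 1.0] + rng.normal(0, noise, 3))
        return pd.DataFrame(rows, columns=["NV-F", "NV-M", "NE-F"])

    def test_clean_two_pattern_labels(self, rng):
        mat = self._clean_patterns(rng)
        out = chrom.hierarchical_ne_states(mat, k_cut=2)
        assert (out["ne_state"][:60] == "NE-open").all()
        assert (out["ne_state"][60:] == "NE-close").all()

    def test_label_matches_centroid_pattern_rule(self, rng):
        mat = self._clean_patterns(rng, n_open=80, n_close=50)
        out = chrom.hierarchical_ne_states(mat, k_cut=4)
        Z = chrom.zscale_rows(mat)
        for c in out["cluster"].unique():
            cent = Z[(out["cluster"] == c).to_numpy()].mean(axis=0)
            lab = set(out.loc[out["cluster"] == c, "ne_state"])
            if "NE-open" in lab:
                assert cent["NV-M"] > cent["NV-F"] and cent["NE-F"] > cent["NV-F"]
            if "NE-close" in lab:
                assert cent["NV-M"] < cent["NV-F"] and cent["NE-F"] < cent["NV-F"]

    def test_invariant_to_row_order_and_uniform_scaling(self, rng):
        mat = self._clean_patterns(rng)
        out1 = chrom.hierarchical_ne_states(mat, k_cut=3)
        perm = rng.permutation(len(mat))
        out2 = chrom.hierarchical_ne_states(mat.iloc[perm], k_cut=3)
        assert (out2["ne_state"].sort_index()
                == out1["ne_state"].sort_index()).all()
        out3 = chrom.hierarchical_ne_states(mat * 10.0, k_cut=3)
        assert (out3["ne_state"] == out1["ne_state"]).all()

    def test_planted_three_group_instance_labelled_correctly(self):
        cfg = SimulationConfig(seed=13, n_peaks=1200)
        counts, design, peaks, truth = generate_condition_atac(
            cfg, groups=neonatal_three_group_groups(),
            archetypes=NEONATAL_ARCHETYPES,
            peaks_per_archetype={k: v // 2 for k, v in
                                 NEONATAL_ARCHETYPE_SIZES.items()})
        res = chrom.multi_condition_test(counts, design, factors=("group",),
                                         contrast="anova")
        diff = res.index[res["p_adj"] < 0.05]
        grp = chrom.cpm(counts).T.groupby(design["group"]).mean().T
        ne = chrom.hierarchical_ne_states(grp.loc[diff], k_cut=6)
        lab = truth.peak_archetypes.reindex(ne.index)
        for state in ("NE-open", "NE-close"):
            called = ne.index[ne["ne_state"] == state]
            assert len(called) > 0
            assert (lab[called] == state).mean() > 0.9

    def test_k_cut_larger_than_peaks_rejected(self, rng):
        with pytest.raises(ValueError):
            chrom.hierarchical_ne_states(self._clean_patterns(rng, 3, 2),
                                         k_cut=50)


class TestSexDifferenceProfile:
    def test_low_abundance_cluster_excluded(self, small_multiome):
        rna, atac, peaks, truth = small_multiome
        loci = list(truth.sex_biased_peaks["peak"])
        out = chrom.sex_difference_profile(
            atac, loci, k=4, min_cells_per_cluster=10_000)
        # every cluster below the bar -> empty difference matrix
        assert out.centroids.empty or out.centroids.shape[1] == 0

    def test_planted_male_open_loci_separate_from_null(self, small_multiome):
        rna, atac, peaks, truth = small_multiome
        sex_loci = list(truth.sex_biased_peaks["peak"])
        null_loci = [p for p in atac.var_names
                     if p not in set(sex_loci)][: len(sex_loci)]
        out = chrom.sex_difference_profile(
            atac, sex_loci + null_loci, k=2, min_cells_per_cluster=50, seed=0)
        lab = out.labels
        planted = lab[sex_loci].mode()[0]
        assert (lab[sex_loci] == planted).mean() > 0.8
        assert (lab[null_loci] == planted).mean() < 0.5


class TestMaintenance:
    def test_identical_and_disjoint_sets(self):
        from regulome.intervals import PeakSet
        a = PeakSet(pd.DataFrame({"chrom": ["chr1"] * 3,
                                  "start": [0, 100, 200],
                                  "end": [50, 150, 250]}))
        b = PeakSet(pd.DataFrame({"chrom": ["chr1"],
                                  "start": [500], "end": [600]}))
        assert chrom.maintenance_overlap(a, a)[0] == 1.0
        assert chrom.maintenance_overlap(a, b)[0] == 0.0
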