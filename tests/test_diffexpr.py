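"""Normalization, dispersion, NB Wald test, BH, batch removal, ordination."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from coralfront import diffexpr, synth


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        counts = pd.DataFrame({"a": [5, 9, 14], "b": [5, 9, 14]},
                              index=["g1", "g2", "g3"])
        sf = diffexpr.estimate_size_factors(counts)
        assert np.allclose(sf, 1.0)

    def test_doubled_sample_by_hand(self, small_counts):
        # geometric means sqrt(2)*[10,20,30]; ratios 1/sqrt2 and sqrt2
        sf = diffexpr.estimate_size_factors(small_counts)
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2), abs=1e-4)
        assert sf["s2"] == pytest.approx(np.sqrt(2), abs=1e-4)

    def test_zero_containing_gene_is_ignored(self, small_counts):
        with_zero = pd.concat([
            small_counts,
            pd.DataFrame({"s1": [0], "s2": [1000]}, index=["g4"])])
        assert np.allclose(diffexpr.estimate_size_factors(with_zero),
                           diffexpr.estimate_size_factors(small_counts))

    def test_scaling_one_sample_scales_its_relative_factor(self, rng):
        # factors are defined relative to the per-gene geometric-mean
        # reference, so scaling one sample by c scales its factor by c
        # relative to every other sample's
        counts = pd.DataFrame(rng.integers(1, 200, size=(50, 4)),
                              columns=list("abcd"))
        sf = diffexpr.estimate_size_factors(counts)
        scaled = counts.copy()
        scaled["c"] = scaled["c"] * 3
        sf2 = diffexpr.estimate_size_factors(scaled)
        for other in "abd":
            assert (sf2["c"] / sf2[other]) == pytest.approx(
                3 * sf["c"] / sf[other], rel=1e-9)

    def test_all_zero_reference_rejected(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="median-of-ratios"):
            diffexpr.estimate_size_factors(counts)


class TestDispersions:
    def test_poisson_counts_yield_near_zero_dispersion(self, rng):
        counts = pd.DataFrame(rng.poisson(100, size=(1000, 12)))
        disp = diffexpr.estimate_dispersions(counts)["dispersion"]
        assert disp.median() < 0.01

    def test_nb_dispersion_recovered(self, rng):
        alpha = 0.5
        lam = rng.gamma(1 / alpha, 100 * alpha, size=(1000, 12))
        counts = pd.DataFrame(rng.poisson(lam))
        disp = diffexpr.estimate_dispersions(counts)["dispersion"]
        assert 0.3 < disp.median() < 0.7

    def test_all_zero_gene_floored_and_flagged(self, rng):
        counts = pd.DataFrame(rng.poisson(50, size=(20, 6)))
        counts.iloc[0] = 0
        out = diffexpr.estimate_dispersions(counts)
        assert out.iloc[0]["all_zero"]
        assert out.iloc[0]["dispersion"] == pytest.approx(1e-8)

    def test_design_projection_removes_group_signal(self, rng):
        # a strong two-group mean shift must not inflate dispersion
        base = rng.poisson(100, size=(500, 10)).astype(float)
        base[:, 5:] *= 4.0
        counts = pd.DataFrame(base.astype(int))
        X = np.column_stack([np.ones(10), np.repeat([0, 1], 5)])
        sf = pd.Series(1.0, index=counts.columns)
        with_design = diffexpr.estimate_dispersions(
            counts, sf, design=X)["dispersion"]
        without = diffexpr.estimate_dispersions(counts, sf)["dispersion"]
        assert with_design.median() < 0.05
        assert without.median() > 0.2


class TestWaldTest:
    def _simulate(self, seed, preset="null"):
        design, params = synth.get_preset(preset, seed=seed)
        return synth.simulate_counts(design, params)

    def test_identical_groups_give_null_results(self):
        counts = pd.DataFrame(
            np.tile([[100], [50], [200]], (1, 8)),
            index=["g1", "g2", "g3"],
            columns=[f"s{i}" for i in range(8)])
        meta = pd.DataFrame({
            "sample_id": counts.columns,
            "entity": ["chimera"] * 4 + ["nonchimera"] * 4,
            "depth": ["10m"] * 8,
            "mother_colony": list("ABAB") * 2})
        res = diffexpr.wald_nb_test(counts, meta,
                                    contrast=("entity", "chimera",
                                              "nonchimera"))
        assert np.allclose(res["log2fc"], 0.0, atol=1e-6)
        assert (res["pvalue"] > 0.99).all()

    def test_null_simulation_p_values_uniform(self):
        counts, meta, _ = self._simulate(42)
        sub = meta[meta.depth == "10m"]
        res = diffexpr.wald_nb_test(counts[list(sub.sample_id)], sub,
                                    contrast=("entity", "chimera",
                                              "nonchimera"))
        ks = stats.kstest(res["pvalue"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_large_planted_effect_detected(self):
        counts, meta, truth = self._simulate(43, preset="paper-like")
        sub = meta[meta.entity == "nonchimera"]
        res = diffexpr.wald_nb_test(counts[list(sub.sample_id)], sub,
                                    contrast=("depth", "2m", "10m"))
        responsive = truth.index[truth != "NULL"]
        assert (res.loc[responsive, "fdr"] < 0.05).mean() > 0.9

    def test_log2fc_matches_group_mean_ratio_in_easy_limit(self, rng):
        # no covariate, equal library sizes, large counts
        mu = np.array([200.0] * 6 + [800.0] * 6)
        counts = pd.DataFrame(rng.poisson(np.tile(mu, (300, 1))),
                              columns=[f"s{i}" for i in range(12)])
        meta = pd.DataFrame({
            "sample_id": counts.columns,
            "group": ["a"] * 6 + ["b"] * 6})
        sf = pd.Series(1.0, index=counts.columns)
        res = diffexpr.wald_nb_test(counts, meta,
                                    contrast=("group", "b", "a"),
                                    covariates=(), size_factors=sf)
        q = counts.to_numpy(float)
        expected = np.log2(q[:, 6:].mean(1) / q[:, :6].mean(1))
        assert np.allclose(res["log2fc"], expected, atol=1e-2)

    def test_wald_statistic_definition_holds(self):
        counts, meta, _ = self._simulate(44)
        sub = meta[meta.depth == "10m"]
        res = diffexpr.wald_nb_test(counts[list(sub.sample_id)], sub,
                                    contrast=("entity", "chimera",
                                              "nonchimera")).dropna()
        assert np.allclose(np.abs(res["stat"]),
                           np.abs(res["log2fc"] / res["se"]), rtol=1e-9)

    def test_confounded_design_rejected(self):
        counts = pd.DataFrame(np.ones((5, 4), dtype=int) * 10,
                              columns=list("abcd"))
        meta = pd.DataFrame({
            "sample_id": list("abcd"),
            "entity": ["chimera", "chimera", "nonchimera", "nonchimera"],
            "depth": ["10m"] * 4,
            "mother_colony": ["A", "A", "B", "B"]})   # mother == entity
        with pytest.raises(ValueError, match="rank deficient"):
            diffexpr.wald_nb_test(counts, meta,
                                  contrast=("entity", "chimera",
                                            "nonchimera"))


class TestBHAdjust:
    def test_step_up_by_hand(self):
        assert np.allclose(diffexpr.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])
        assert np.allclose(diffexpr.bh_adjust([0.001, 0.5]), [0.002, 0.5])
        assert diffexpr.bh_adjust([0.3]) == pytest.approx([0.3])

    def test_preserves_input_order_and_nan(self):
        out = diffexpr.bh_adjust([0.5, np.nan, 0.001])
        assert np.isnan(out[1])
        assert out[2] < out[0]

    def test_matches_statsmodels_reference(self, rng):
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            ours = diffexpr.bh_adjust(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, ref, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            diffexpr.bh_adjust([0.5, 1.5])


class TestBatchRemoval:
    def test_single_batch_is_identity(self, rng):
        x = pd.DataFrame(rng.normal(size=(20, 6)),
                         columns=[f"s{i}" for i in range(6)])
        batch = pd.Series(["A"] * 6, index=x.columns)
        assert np.allclose(diffexpr.remove_batch_effect(x, batch), x)

    def test_pure_offsets_equalized_to_grand_mean(self):
        x = pd.DataFrame({"a": [1.0, 5.0], "b": [2.0, 6.0],
                          "c": [11.0, 15.0], "d": [12.0, 16.0]})
        batch = pd.Series(["A", "A", "B", "B"], index=x.columns)
        adj = diffexpr.remove_batch_effect(x, batch)
        for g in adj.index:
            mean_a = adj.loc[g, ["a", "b"]].mean()
            mean_b = adj.loc[g, ["c", "d"]].mean()
            assert mean_a == pytest.approx(mean_b, abs=1e-10)
            assert mean_a == pytest.approx(x.loc[g].mean(), abs=1e-10)

    def test_retained_treatment_difference_preserved(self, rng):
        n = 8
        treat = np.repeat([0.0, 1.0], n // 2)
        batch_labels = pd.Series(list("ABAB") * 2)
        effect = 3.0
        base = rng.normal(size=(30, n))
        offsets = np.where(batch_labels == "A", 1.5, -1.5)
        data = base + effect * treat + offsets
        x = pd.DataFrame(data, columns=[f"s{i}" for i in range(n)])
        batch_labels.index = x.columns
        design = pd.DataFrame({"treat": treat}, index=x.columns)
        adj = diffexpr.remove_batch_effect(x, batch_labels, design=design)
        raw_diff = (x.loc[:, treat == 1].mean(1) - x.loc[:, treat == 0].mean(1))
        adj_diff = (adj.loc[:, treat == 1].mean(1)
                    - adj.loc[:, treat == 0].mean(1))
        assert np.allclose(adj_diff, raw_diff, atol=1e-9)

    def test_confounded_batch_rejected(self):
        x = pd.DataFrame(np.ones((3, 4)), columns=list("abcd"))
        batch = pd.Series(["A", "A", "B", "B"], index=x.columns)
        design = pd.DataFrame({"t": [0.0, 0.0, 1.0, 1.0]}, index=x.columns)
        with pytest.raises(ValueError, match="confounded"):
            diffexpr.remove_batch_effect(x, batch, design=design)


class TestOrdination:
    def test_duplicated_sample_at_zero_distance(self, rng):
        x = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        x["d"] = x["a"]
        out = diffexpr.sample_ordination(x)
        assert out["distance"].loc["a", "d"] == pytest.approx(0.0)
        # zero-distance pair merges first in the dendrogram
        assert out["linkage"][0, 2] == pytest.approx(0.0)

    def test_explained_variance_sums_to_one(self, rng):
        x = pd.DataFrame(rng.normal(size=(30, 6)))
        out = diffexpr.sample_ordination(x)
        assert out["explained_variance"].sum() == pytest.approx(1.0)

    def test_entity_effect_separates_on_first_pc(self):
        # entity effect made dominant: many frontloaded genes, weak response
        import dataclasses
        design, params = synth.get_preset("paper-like", seed=5)
        params = dataclasses.replace(
            params, n_per_category={"FRONTLOADED": 300},
            response_lfc=0.5, basal_shift_lfc=3.0)
        counts, meta, _ = synth.simulate_counts(design, params)
        logx = diffexpr.rlog_like(counts)
        out = diffexpr.sample_ordination(logx)
        pc1 = out["coordinates"]["PC1"]
        entity = meta.set_index("sample_id").loc[pc1.index, "entity"]
        chim = pc1[entity == "chimera"]
        nonc = pc1[entity == "nonchimera"]
        # the groups separate: silhouette-like gap on PC1
        assert min(chim.max(), nonc.max()) < max(chim.min(), nonc.min()) \
            or abs(chim.mean() - nonc.mean()) > (chim.std() + nonc.std())

    def test_too_few_samples_rejected(self, rng):
        x = pd.DataFrame(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match="3 samples"):
            diffexpr.sample_ordination(x)
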