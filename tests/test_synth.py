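"""Synthetic-data generators: determinism, moments, planted structure."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from coralfront import synth
from coralfront.chimerism import summarize_variant_frame
from coralfront.synth import (LoggerProfile, SimDesign, SimParams,
                              simulate_counts, simulate_go_annotation,
                              simulate_logger, simulate_otu_table,
                              simulate_survival_counts,
                              simulate_variant_table)


def small_design(seed=0, n_genes=300):
    return SimDesign(n_genes=n_genes,
                     replicates={(e, d): 3 for e in synth.ENTITIES
                                 for d in synth.DEPTHS},
                     mothers=("A", "B", "C"), seed=seed)


class TestCounts:
    def test_same_seed_reproduces_identical_output(self):
        d, p = small_design(seed=9), SimParams(n_per_category={})
        a = simulate_counts(d, p)
        b = simulate_counts(d, p)
        assert a[0].equals(b[0]) and a[1].equals(b[1]) and a[2].equals(b[2])

    def test_different_seed_differs(self):
        p = SimParams(n_per_category={})
        a = simulate_counts(small_design(seed=1), p)[0]
        b = simulate_counts(small_design(seed=2), p)[0]
        assert not a.equals(b)

    def test_poisson_limit_matches_baseline_mean(self):
        # dispersion -> 0, no effects: per-gene sample mean within 3
        # Monte-Carlo standard errors of exp(baseline)
        design = SimDesign(n_genes=1000,
                           replicates={(e, d): 5 for e in synth.ENTITIES
                                       for d in synth.DEPTHS},
                           mothers=("A",), seed=3)
        params = SimParams(baseline_logmean_mean=4.0,
                           baseline_logmean_sd=0.0, dispersion=0.0,
                           batch_sd=0.0, n_per_category={})
        counts, _, _ = simulate_counts(design, params)
        mu = np.exp(4.0)
        sample_means = counts.mean(axis=1)
        se = np.sqrt(mu / counts.shape[1])
        within = np.abs(sample_means - mu) <= 3 * se
        assert within.mean() > 0.99 - 3 * np.sqrt(0.99 * 0.01 / 1000)

    def test_frontloaded_basal_ratio(self):
        # basal_shift_lfc=2 -> chimera/non-chimera mean ratio ~ 4 at 10m
        design = SimDesign(n_genes=2000,
                           replicates={(e, d): 10 for e in synth.ENTITIES
                                       for d in synth.DEPTHS},
                           mothers=("A",), seed=4)
        params = SimParams(basal_shift_lfc=2.0, batch_sd=0.0,
                           n_per_category={"FRONTLOADED": 500})
        counts, meta, truth = simulate_counts(design, params)
        front = truth.index[truth == "FRONTLOADED"]
        chim = meta.loc[(meta.entity == "chimera")
                        & (meta.depth == "10m"), "sample_id"]
        nonc = meta.loc[(meta.entity == "nonchimera")
                        & (meta.depth == "10m"), "sample_id"]
        ratio = (counts.loc[front, chim].to_numpy().mean()
                 / counts.loc[front, nonc].to_numpy().mean())
        assert ratio == pytest.approx(4.0, rel=0.1)

    def test_nb_moments(self):
        # empirical variance ~ mu + dispersion * mu^2 at many draws
        design = SimDesign(n_genes=1, replicates={(e, d): 5000
                                                  for e in synth.ENTITIES
                                                  for d in synth.DEPTHS},
                           mothers=("A",), seed=5)
        params = SimParams(baseline_logmean_mean=4.0,
                           baseline_logmean_sd=0.0, dispersion=0.2,
                           batch_sd=0.0, n_per_category={})
        counts, _, _ = simulate_counts(design, params)
        x = counts.iloc[0].to_numpy(dtype=float)
        mu = np.exp(4.0)
        assert x.mean() == pytest.approx(mu, rel=0.05)
        assert x.var() == pytest.approx(mu + 0.2 * mu ** 2, rel=0.1)

    def test_planted_sets_disjoint_and_cover_all_genes(self):
        design, params = synth.get_preset("paper-like", seed=6)
        _, _, truth = simulate_counts(design, params)
        vc = truth.value_counts()
        assert vc["FRONTLOADED"] == 60
        assert vc["HIGHER_PLASTICITY"] == 60
        assert vc["FRONTLOADED_AND_HIGHER_PLASTICITY"] == 60
        assert vc["RESPONSIVE_ONLY"] == 200
        assert vc.sum() == design.n_genes

    def test_empty_design_cell_rejected(self):
        design = small_design()
        design.replicates[("chimera", "2m")] = 0
        with pytest.raises(ValueError, match="chimera"):
            simulate_counts(design, SimParams())

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError, match="dispersion"):
            simulate_counts(small_design(), SimParams(dispersion=-1.0))


class TestGOAnnotation:
    def test_planted_term_round_trips(self, tmp_path):
        from coralfront import io
        planted = {"GO:PLANT": {f"gene{i:05d}" for i in range(30)}}
        ann = simulate_go_annotation(200, n_terms=10, planted=planted,
                                     seed=1)
        path = tmp_path / "gene2go.tsv"
        io.write_go_annotation(ann, path)
        back = io.read_go_annotation(path)
        members = {g for g, ts in back.gene_terms.items()
                   if "GO:PLANT" in ts}
        assert members == planted["GO:PLANT"]

    def test_no_planted_terms_gives_only_random_terms(self):
        ann = simulate_go_annotation(100, n_terms=5, planted={}, seed=2)
        terms = set().union(*ann.gene_terms.values())
        assert terms <= {f"GO:{t:07d}" for t in range(5)}

    def test_zero_terms_is_degenerate_but_accepted_downstream(self):
        from coralfront.enrichment import build_go_index
        ann = simulate_go_annotation(50, n_terms=0, planted={}, seed=3)
        idx = build_go_index(ann, [f"gene{i:05d}" for i in range(50)])
        assert idx.categories == []

    def test_planted_term_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            simulate_go_annotation(10, 2, planted={"T": {"gene99999"}},
                                   seed=0)

    def test_parent_links_form_dag(self):
        ann = simulate_go_annotation(300, n_terms=40, seed=4,
                                     with_parents=True)
        for term in list(ann.parents):
            ann.ancestors(term)   # raises on a cycle


class TestVariantTable:
    def test_zero_excess_groups_equal_within_noise(self):
        diffs = []
        for seed in range(30):
            records, meta = simulate_variant_table(
                n_chimera=6, n_nonchimera=6, n_loci=150,
                multiallelic_excess=0.0, seed=seed)
            s = {x.sample_id: x.rel_multiallelic
                 for x in summarize_variant_frame(records)}
            ent = meta.set_index("sample_id")["entity"]
            chim = np.mean([v for k, v in s.items() if ent[k] == "chimera"])
            nonc = np.mean([v for k, v in s.items() if ent[k] != "chimera"])
            diffs.append(chim - nonc)
        assert abs(np.mean(diffs)) < 0.01

    def test_excess_visible_in_group_means(self):
        records, meta = simulate_variant_table(multiallelic_excess=0.3,
                                               seed=1)
        s = {x.sample_id: x.rel_multiallelic
             for x in summarize_variant_frame(records)}
        ent = meta.set_index("sample_id")["entity"]
        chim = np.mean([v for k, v in s.items() if ent[k] == "chimera"])
        nonc = np.mean([v for k, v in s.items() if ent[k] != "chimera"])
        assert chim - nonc == pytest.approx(0.3, abs=0.06)

    def test_emitted_file_parses_as_vcf(self, tmp_path):
        import pysam
        from coralfront import io
        records, _ = simulate_variant_table(n_chimera=1, n_nonchimera=1,
                                            n_loci=10, seed=2)
        paths = io.write_variant_tables(records, tmp_path)
        vf = pysam.VariantFile(str(next(iter(paths.values()))))
        assert vf.header.version.startswith("VCF")
        assert sum(1 for _ in vf) == 10

    def test_zero_loci_rejected(self):
        with pytest.raises(ValueError, match="n_loci"):
            simulate_variant_table(n_loci=0)


class TestLogger:
    def test_record_count_arithmetic(self):
        series = simulate_logger(hours=48, step_minutes=10, seed=0)
        per_depth = series.groupby("depth").size()
        assert (per_depth == 289).all()

    def test_flat_profile_is_constant(self):
        profiles = {"10m": LoggerProfile(25.0, 0.0, 0.0, 0.0)}
        series = simulate_logger(profiles, hours=24, step_minutes=60,
                                 seed=0)
        assert (series["temperature_C"] == 25.0).all()
        assert (series["light_lux"] == 0.0).all()

    def test_light_zero_at_night(self):
        series = simulate_logger(hours=24, step_minutes=60, seed=0)
        hours = pd.to_datetime(series["timestamp"]).dt.hour
        assert (series.loc[(hours < 6) | (hours > 18), "light_lux"]
                == 0.0).all()

    def test_determinism(self):
        a = simulate_logger(hours=12, step_minutes=30, seed=5)
        b = simulate_logger(hours=12, step_minutes=30, seed=5)
        assert a.equals(b)


class TestOTUAndSurvival:
    def test_otu_same_seed_identical(self):
        a = simulate_otu_table(seed=8)[0]
        b = simulate_otu_table(seed=8)[0]
        assert a.equals(b)

    def test_single_otu_community_downstream_shannon_zero(self):
        from coralfront.microbiome import alpha_diversity
        table, _ = simulate_otu_table(n_samples_per_group=2, n_otus=1,
                                      base_proportions=[1.0], seed=0)
        assert (alpha_diversity(table)["shannon"] == 0.0).all()

    def test_negative_library_rejected(self):
        with pytest.raises(ValueError, match="library"):
            simulate_otu_table(library_size=-5)

    def test_survival_monotone_non_increasing(self):
        for seed in range(10):
            t = simulate_survival_counts(timepoints=(3, 6, 9, 12),
                                         seed=seed)
            for _, grp in t.groupby("group"):
                alive = grp.sort_values("timepoint")["n_alive"].tolist()
                assert alive == sorted(alive, reverse=True)

    def test_certain_survival(self):
        t = simulate_survival_counts(n0_per_group=40, rate_chimera=1.0,
                                     rate_nonchimera=1.0, seed=0)
        assert (t["n_alive"] == 40).all()

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError, match="rates"):
            simulate_survival_counts(rate_chimera=1.5)
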