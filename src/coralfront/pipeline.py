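"""End-to-end orchestration of the analysis graph.

Stage order is fixed: differential expression per contrast -> frontloading
classification -> GO enrichment (rank-based per contrast, Fisher on the
frontloaded set) -> batch removal and DAPC plasticity -> chimerism test ->
microbiome diversity -> field statistics.  Inputs come either from files
or from a named synthetic preset; every intermediate is written beside the
report and all randomness flows from the single configuration seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chimerism, diffexpr, enrichment, fieldstats, io, microbiome, \
    plasticity, synth

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_inputs", "run_pipeline", "write_report"]

#: the four DE contrasts: entity within each depth, depth within each entity
CONTRASTS = {
    "entity_at_10m": dict(subset=("depth", "10m"),
                          contrast=("entity", "chimera", "nonchimera")),
    "entity_at_2m": dict(subset=("depth", "2m"),
                         contrast=("entity", "chimera", "nonchimera")),
    "depth_in_nonchimera": dict(subset=("entity", "nonchimera"),
                                contrast=("depth", "2m", "10m")),
    "depth_in_chimera": dict(subset=("entity", "chimera"),
                             contrast=("depth", "2m", "10m")),
}


@dataclass
class PipelineConfig:
    """Resolved run configuration (thresholds echoed into every report)."""

    preset: str | None = "paper-like"
    seed: int = 0
    output_dir: str = "coralfront_out"
    # input paths (used when preset is None)
    counts: str | None = None
    metadata: str | None = None
    go_annotation: str | None = None
    vcf_dir: str | None = None
    otu_table: str | None = None
    logger_csv: str | None = None
    survival_csv: str | None = None
    # thresholds
    alpha: float = 0.05
    go_smallest: int = enrichment.DEFAULT_SMALLEST
    go_largest: float = enrichment.DEFAULT_LARGEST
    go_cut_height: float = enrichment.DEFAULT_CUT_HEIGHT
    mnp_allele_threshold: int = chimerism.DEFAULT_ALLELE_THRESHOLD
    otu_min_fraction: float = 0.01
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.go_largest < 1:
            raise ValueError("go_largest must be in (0, 1)")
        if not 0 <= self.otu_min_fraction < 1:
            raise ValueError("otu_min_fraction must be in [0, 1)")
        if self.preset is None and (self.counts is None
                                    or self.metadata is None):
            raise ValueError("either a preset or counts+metadata paths "
                             "must be given")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _digest(frame: pd.DataFrame) -> str:
    return hashlib.sha256(
        frame.to_csv().encode()).hexdigest()[:16]


def load_inputs(config: PipelineConfig) -> dict:
    """Load (or simulate) every dataset the pipeline consumes.

    Cross-file consistency is enforced: every count-matrix sample must
    have exactly one metadata row.
    """
    config.validate()
    data: dict = {}
    if config.preset is not None:
        design, params = synth.get_preset(config.preset, seed=config.seed)
        counts, metadata, truth = synth.simulate_counts(design, params)
        data["counts"], data["metadata"], data["truth"] = counts, metadata, truth
        rng = np.random.default_rng(config.seed + 1)
        planted = _plant_go_terms(truth, rng)
        data["go"] = synth.simulate_go_annotation(
            n_genes=design.n_genes, n_terms=60, planted=planted,
            seed=config.seed + 2)
        records, vcf_meta = synth.simulate_variant_table(seed=config.seed + 3)
        data["variant_records"], data["variant_metadata"] = records, vcf_meta
        data["logger"] = synth.simulate_logger(seed=config.seed + 4)
        otu, otu_meta = synth.simulate_otu_table(seed=config.seed + 5)
        data["otu"], data["otu_metadata"] = otu, otu_meta
        data["survival"] = synth.simulate_survival_counts(seed=config.seed + 6)
        return data

    data["counts"] = io.read_counts(config.counts)
    data["metadata"] = io.read_metadata(config.metadata)
    missing = set(data["counts"].columns) - set(data["metadata"]["sample_id"])
    if missing:
        raise ValueError(f"metadata missing count-matrix samples: "
                         f"{sorted(missing)}")
    if config.go_annotation:
        data["go"] = io.read_go_annotation(config.go_annotation)
    if config.vcf_dir:
        data["vcf_dir"] = Path(config.vcf_dir)
    if config.otu_table:
        data["otu"] = io.read_otu_table(config.otu_table)
    if config.logger_csv:
        data["logger"] = io.read_logger(config.logger_csv)
    if config.survival_csv:
        data["survival"] = io.read_survival(config.survival_csv)
    return data


def _plant_go_terms(truth: pd.Series, rng: np.random.Generator) -> dict:
    """Plant one GO term per expression archetype (for recovery checks)."""
    planted = {}
    for cat, term in (("FRONTLOADED", "GO:9000001"),
                      ("HIGHER_PLASTICITY", "GO:9000002"),
                      ("RESPONSIVE_ONLY", "GO:9000003")):
        genes = truth.index[truth == cat]
        if len(genes) >= 10:
            size = min(len(genes), 30)
            planted[term] = set(rng.choice(genes, size=size, replace=False))
    return planted


def _subset(counts: pd.DataFrame, metadata: pd.DataFrame,
            column: str, value: str):
    keep = metadata.loc[metadata[column] == value, "sample_id"]
    return counts[list(keep)], metadata[metadata[column] == value]


def run_pipeline(config: PipelineConfig, write: bool = True) -> dict:
    """Execute the full analysis graph; returns the run report.

    Stage failures are recorded in the report and their downstream
    dependents skipped; the report carries ``ok=False`` in that case.
    """
    config.validate()
    outdir = Path(config.output_dir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
    data = load_inputs(config)
    report: dict = {"config": dataclasses.asdict(config), "stages": {},
                    "ok": True}

    def stage(name):
        def deco(fn):
            entry = {"status": "ok", "warnings": []}
            try:
                entry.update(fn() or {})
            except Exception as exc:   # recorded, dependents skipped
                logger.exception("stage %s failed", name)
                entry["status"] = "failed"
                entry["error"] = str(exc)
                report["ok"] = False
            report["stages"][name] = entry
            return entry
        return deco

    counts, metadata = data["counts"], data["metadata"]
    results: dict[str, pd.DataFrame] = {}

    @stage("differential_expression")
    def _de():
        out = {"inputs_digest": _digest(counts), "contrasts": {}}
        for name, spec in CONTRASTS.items():
            sub_counts, sub_meta = _subset(counts, metadata, *spec["subset"])
            res = diffexpr.wald_nb_test(sub_counts, sub_meta,
                                        contrast=spec["contrast"])
            results[name] = res
            if write:
                io.write_de_result(res, outdir / f"de_{name}.tsv")
            out["contrasts"][name] = {
                "n_significant": int((res["fdr"] < config.alpha).sum()),
                "n_tested": int(res["pvalue"].notna().sum()),
            }
        return out

    @stage("classification")
    def _classify():
        if "depth_in_nonchimera" not in results:
            raise RuntimeError("differential expression did not run")
        cls = plasticity.classify_frontloading(
            results["depth_in_nonchimera"], results["entity_at_10m"],
            results["depth_in_chimera"], alpha=config.alpha)
        results["classification"] = cls
        if write:
            cls.to_csv(outdir / "classification.tsv", sep="\t")
        counts_by_cat = cls["category"].value_counts().to_dict() if len(cls) else {}
        return {"n_entering": int(len(cls)),
                "category_counts": {k: int(v) for k, v in counts_by_cat.items()}}

    @stage("enrichment")
    def _enrich():
        if "go" not in data:
            return {"status": "skipped", "reason": "no GO annotation"}
        if "depth_in_nonchimera" not in results:
            raise RuntimeError("differential expression did not run")
        universe = [g for g in counts.index
                    if np.isfinite(results["depth_in_nonchimera"]
                                   .at[g, "log2fc"])]
        index = enrichment.build_go_index(
            data["go"], universe, smallest=config.go_smallest,
            largest=config.go_largest)
        index = enrichment.cluster_go_terms(
            index, cut_height=config.go_cut_height,
            largest=config.go_largest)
        out = {"n_categories": len(index.categories), "mwu": {}}
        mwu_results = {}
        for name in ("depth_in_nonchimera", "depth_in_chimera"):
            measure = results[name]["log2fc"].reindex(universe)
            res = enrichment.mwu_enrichment(measure, index)
            mwu_results[name] = res
            if write and len(res):
                res.drop(columns="genes").to_csv(
                    outdir / f"enrichment_mwu_{name}.tsv", sep="\t",
                    index=False)
            out["mwu"][name] = int((res["fdr"] < config.alpha).sum()) \
                if len(res) else 0
        cls = results.get("classification")
        if cls is not None and len(cls):
            flag = pd.Series(False, index=pd.Index(universe))
            front = cls.index[cls["category"].isin(
                ["FRONTLOADED", "FRONTLOADED_AND_HIGHER_PLASTICITY"])]
            flag.loc[flag.index.intersection(front)] = True
            if flag.any() and not flag.all():
                fres = enrichment.fisher_enrichment(flag, index)
                if write and len(fres):
                    fres.drop(columns="genes").to_csv(
                        outdir / "enrichment_fisher_frontloaded.tsv",
                        sep="\t", index=False)
                out["fisher_frontloaded"] = int(
                    (fres["fdr"] < config.alpha).sum()) if len(fres) else 0
        a = mwu_results["depth_in_nonchimera"]
        b = mwu_results["depth_in_chimera"]
        if len(a) >= 3 and len(b) >= 3:
            r, _ = enrichment.delta_rank_correlation(a, b)
            out["delta_rank_correlation"] = r
        return out

    @stage("plasticity_dapc")
    def _dapc():
        sf = diffexpr.estimate_size_factors(counts)
        logx = diffexpr.rlog_like(counts, sf)
        meta_idx = metadata.set_index("sample_id")
        depth_design = pd.get_dummies(
            meta_idx.loc[logx.columns, "depth"], drop_first=True)
        adjusted = diffexpr.remove_batch_effect(
            logx, meta_idx.loc[logx.columns, "mother_colony"],
            design=depth_design)
        nonchim = meta_idx.index[meta_idx["entity"] == "nonchimera"]
        model = plasticity.fit_dapc(adjusted[list(nonchim)],
                                    meta_idx.loc[nonchim, "depth"])
        coords = plasticity.project_dapc(model, adjusted)
        frame = pd.DataFrame({
            "coord": coords,
            "entity": meta_idx.loc[coords.index, "entity"],
            "depth": meta_idx.loc[coords.index, "depth"]})
        metrics = plasticity.plasticity_metrics(frame)
        if write:
            frame.to_csv(outdir / "dapc_coordinates.tsv", sep="\t")
            with open(outdir / "plasticity_metrics.json", "w") as fh:
                json.dump(metrics, fh, indent=2)
        return {"metrics": metrics, "n_pcs": model.n_pcs}

    @stage("chimerism")
    def _chim():
        if "variant_records" in data:
            vcf_dir = outdir / "vcf" if write else None
            if write:
                paths = io.write_variant_tables(data["variant_records"],
                                                vcf_dir)
                summaries = [chimerism.extract_mnp_summary(
                    p, allele_threshold=config.mnp_allele_threshold)
                    for p in paths.values()]
            else:
                summaries = chimerism.summarize_variant_frame(
                    data["variant_records"], config.mnp_allele_threshold)
            meta = data["variant_metadata"]
        elif "vcf_dir" in data:
            summaries = [chimerism.extract_mnp_summary(
                p, allele_threshold=config.mnp_allele_threshold)
                for p in sorted(data["vcf_dir"].glob("*.vcf"))]
            meta = metadata
        else:
            return {"status": "skipped", "reason": "no variant data"}
        res = chimerism.test_multiallelic_enrichment(summaries, meta)
        if write:
            pd.DataFrame([dataclasses.asdict(s) for s in summaries]).to_csv(
                outdir / "mnp_summaries.tsv", sep="\t", index=False)
        return {"u_statistic": res.u_statistic, "p_value": res.p_value,
                "method": res.method,
                "allele_threshold": config.mnp_allele_threshold}

    @stage("microbiome")
    def _micro():
        if "otu" not in data:
            return {"status": "skipped", "reason": "no OTU table"}
        table = microbiome.filter_otu_table(
            data["otu"], min_fraction=config.otu_min_fraction)
        if table.empty:
            return {"status": "skipped", "reason": "empty after filtering"}
        alpha = microbiome.alpha_diversity(table)
        bc = microbiome.bray_curtis_matrix(table)
        ord_res = microbiome.pcoa(bc)
        meta = data.get("otu_metadata", metadata)
        tests = microbiome.test_alpha_diversity(alpha, meta)
        if write:
            alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
            bc.to_csv(outdir / "bray_curtis.tsv", sep="\t")
            ord_res["coordinates"].to_csv(outdir / "pcoa.tsv", sep="\t")
            tests.to_csv(outdir / "alpha_tests.tsv", sep="\t")
        return {"n_otus_kept": int(table.shape[0]),
                "n_removed": int(table.attrs.get("n_removed", 0)),
                "alpha_tests": tests[["F", "pvalue", "fdr"]]
                .round(6).to_dict("index")}

    @stage("field_stats")
    def _field():
        out = {}
        if "logger" in data:
            env = fieldstats.summarize_logger(data["logger"])
            out["environment"] = {d: s.as_dict() for d, s in env.items()}
        if "survival" in data:
            surv = fieldstats.survival_report(data["survival"])
            if write:
                surv.to_csv(outdir / "survival_tests.tsv", sep="\t",
                            index=False)
            out["survival"] = surv.round(6).to_dict("records")
        if not out:
            return {"status": "skipped", "reason": "no field data"}
        return out

    if "truth" in data and "classification" in results:
        report["recovery"] = _recovery(results["classification"],
                                       data["truth"])
    if write:
        write_report(report, outdir)
    return report


def _recovery(classification: pd.DataFrame, truth: pd.Series) -> dict:
    """Planted-category recall and null false-classification rate."""
    out: dict = {"per_category_recall": {}}
    mapping = {"FRONTLOADED": "FRONTLOADED",
               "HIGHER_PLASTICITY": "HIGHER_PLASTICITY",
               "FRONTLOADED_AND_HIGHER_PLASTICITY":
                   "FRONTLOADED_AND_HIGHER_PLASTICITY"}
    for true_cat, want in mapping.items():
        genes = truth.index[truth == true_cat]
        if not len(genes):
            continue
        got = classification.reindex(genes)["category"]
        out["per_category_recall"][true_cat] = float((got == want).mean())
    null_genes = truth.index[truth == "NULL"]
    classified = classification.index.intersection(null_genes)
    misclassified = classification.loc[classified, "category"] != "UNCLASSIFIED"
    out["null_false_classification_rate"] = \
        float(misclassified.sum() / max(len(null_genes), 1))
    return out


def write_report(report: dict, outdir) -> None:
    """Machine-readable JSON plus a one-line-per-stage text summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    lines = []
    for name, entry in report["stages"].items():
        status = entry.get("status", "ok")
        keys = [k for k in entry if k not in ("status", "warnings")]
        lines.append(f"{name}\t{status}\t{', '.join(keys)}")
    (outdir / "report_summary.tsv").write_text(
        "stage\tstatus\toutputs\n" + "\n".join(lines) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
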