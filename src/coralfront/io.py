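"""Readers and writers for the pipeline's interchange formats.

All tabular formats are plain text: counts and OTU tables as TSV (first
column the feature id), sample metadata / logger / survival / microsatellite
tables as CSV, gene-to-GO maps as two-column TSV, variant calls as VCF
v4.2.  Every writer has a matching reader and round-trips exactly.  Readers
validate schemas and raise informative errors rather than propagating
pandas internals.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chimerism import MicrosatGenotype
from .enrichment import GOAnnotation

__all__ = [
    "read_counts", "write_counts",
    "read_metadata", "write_metadata",
    "read_de_result", "write_de_result",
    "read_go_annotation", "write_go_annotation",
    "read_otu_table", "write_otu_table", "read_biom_json",
    "read_logger", "write_logger",
    "read_survival", "write_survival",
    "read_microsat", "write_microsat",
    "write_vcf", "write_variant_tables",
]


def _read_table(path, sep, index_col, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    try:
        frame = pd.read_csv(path, sep=sep, index_col=index_col)
    except Exception as exc:
        raise ValueError(f"cannot parse {what} file {path}: {exc}") from exc
    if frame.empty and frame.columns.empty:
        raise ValueError(f"{what} file {path} is empty")
    return frame


# -- counts ---------------------------------------------------------------

def read_counts(path) -> pd.DataFrame:
    """Genes x samples TSV; first column ``gene_id``."""
    frame = _read_table(path, "\t", 0, "count matrix")
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups[:5]}")
    if frame.columns.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    try:
        mat = frame.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-integer counts in {path}: {exc}") from exc
    if (mat.to_numpy() < 0).any():
        raise ValueError(f"negative counts in {path}")
    mat.index.name = "gene_id"
    return mat


def write_counts(counts: pd.DataFrame, path) -> None:
    out = counts.copy()
    out.index.name = out.index.name or "gene_id"
    out.to_csv(path, sep="\t")


# -- sample metadata ------------------------------------------------------

_META_COLUMNS = ["sample_id", "entity", "depth", "mother_colony"]


def read_metadata(path) -> pd.DataFrame:
    frame = _read_table(path, ",", None, "sample metadata")
    missing = set(_META_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"metadata {path} missing columns {sorted(missing)}")
    if frame["sample_id"].duplicated().any():
        raise ValueError(f"duplicate sample ids in metadata {path}")
    bad = set(frame["entity"]) - {"chimera", "nonchimera"}
    if bad:
        raise ValueError(f"unknown entity labels in {path}: {sorted(bad)}")
    return frame[_META_COLUMNS].astype(str)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata[_META_COLUMNS].to_csv(path, index=False)


# -- DE results -----------------------------------------------------------

_DE_COLUMNS = ["base_mean", "log2fc", "se", "stat", "pvalue", "fdr"]


def read_de_result(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"DE result file not found: {path}")
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as exc:
        raise ValueError(f"cannot parse DE result file {path}: {exc}") from exc
    missing = set(_DE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"DE result {path} missing columns {sorted(missing)}")
    return frame[_DE_COLUMNS].astype(float)


def write_de_result(result: pd.DataFrame, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        contrast = result.attrs.get("contrast")
        if contrast:
            fh.write(f"# contrast: {contrast}\n")
    result[_DE_COLUMNS].to_csv(path, sep="\t", mode="a",
                               index_label="gene_id")


# -- GO annotation --------------------------------------------------------

def read_go_annotation(path, parents_path=None, obo_path=None
                       ) -> GOAnnotation:
    """Two-column ``gene<TAB>term`` TSV, optionally with parent links.

    Parent links come either from a two-column ``child<TAB>parent`` TSV or
    from a minimal OBO subset (only ``id:`` and ``is_a:`` lines are used).
    """
    gene_terms: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-"
                                 f"separated fields, got {len(parts)}")
            gene, term = parts
            gene_terms.setdefault(gene, set()).add(term)
    parents: dict[str, set] = {}
    names: dict[str, str] = {}
    if parents_path is not None:
        with open(parents_path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\r\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{parents_path}:{lineno}: expected "
                                     "two tab-separated fields")
                child, parent = parts
                parents.setdefault(child, set()).add(parent)
    if obo_path is not None:
        current = None
        with open(obo_path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("id:"):
                    current = line.split("id:", 1)[1].strip()
                elif line.startswith("name:") and current:
                    names[current] = line.split("name:", 1)[1].strip()
                elif line.startswith("is_a:") and current:
                    parent = line.split("is_a:", 1)[1].split("!")[0].strip()
                    parents.setdefault(current, set()).add(parent)
    return GOAnnotation(gene_terms=gene_terms, parents=parents,
                        term_names=names)


def write_go_annotation(annotation: GOAnnotation, path,
                        parents_path=None) -> None:
    with open(path, "w") as fh:
        for gene in sorted(annotation.gene_terms):
            for term in sorted(annotation.gene_terms[gene]):
                fh.write(f"{gene}\t{term}\n")
    if parents_path is not None:
        with open(parents_path, "w") as fh:
            for child in sorted(annotation.parents):
                for parent in sorted(annotation.parents[child]):
                    fh.write(f"{child}\t{parent}\n")


# -- OTU tables -----------------------------------------------------------

def read_otu_table(path) -> pd.DataFrame:
    frame = _read_table(path, "\t", 0, "OTU table")
    if frame.index.has_duplicates:
        raise ValueError(f"duplicate OTU ids in {path}")
    mat = frame.astype(np.int64)
    if (mat.to_numpy() < 0).any():
        raise ValueError(f"negative counts in {path}")
    mat.index.name = "otu_id"
    return mat


def write_otu_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = out.index.name or "otu_id"
    out.to_csv(path, sep="\t")


def read_biom_json(path) -> pd.DataFrame:
    """Minimal BIOM 1.0 (JSON) reader for dense or sparse OTU tables."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        otu_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        shape = tuple(doc["shape"])
        mat = np.zeros(shape)
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                mat[int(i), int(j)] = v
        else:
            mat = np.asarray(doc["data"], dtype=float)
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed BIOM-JSON file {path}: {exc}") from exc
    table = pd.DataFrame(mat.astype(np.int64), index=otu_ids,
                         columns=sample_ids)
    table.index.name = "otu_id"
    return table


# -- logger series --------------------------------------------------------

_LOGGER_COLUMNS = ["timestamp", "temperature_C", "light_lux", "depth"]


def read_logger(path) -> pd.DataFrame:
    frame = _read_table(path, ",", None, "logger series")
    missing = set(_LOGGER_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"logger file {path} missing columns "
                         f"{sorted(missing)}")
    out = frame[_LOGGER_COLUMNS].copy()
    out["temperature_C"] = out["temperature_C"].astype(float)
    out["light_lux"] = out["light_lux"].astype(float)
    return out


def write_logger(series: pd.DataFrame, path) -> None:
    series[_LOGGER_COLUMNS].to_csv(path, index=False)


# -- survival -------------------------------------------------------------

_SURVIVAL_COLUMNS = ["group", "timepoint", "n_alive", "n_total"]


def read_survival(path) -> pd.DataFrame:
    frame = _read_table(path, ",", None, "survival table")
    missing = set(_SURVIVAL_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"survival file {path} missing columns "
                         f"{sorted(missing)}")
    out = frame[_SURVIVAL_COLUMNS].copy()
    out["n_alive"] = out["n_alive"].astype(int)
    out["n_total"] = out["n_total"].astype(int)
    return out


def write_survival(table: pd.DataFrame, path) -> None:
    table[_SURVIVAL_COLUMNS].to_csv(path, index=False)


# -- microsatellites ------------------------------------------------------

def read_microsat(path) -> list[MicrosatGenotype]:
    """Long-format CSV ``sample,locus,allele`` -> genotypes per sample."""
    frame = _read_table(path, ",", None, "microsatellite table")
    missing = {"sample", "locus", "allele"} - set(frame.columns)
    if missing:
        raise ValueError(f"microsatellite file {path} missing columns "
                         f"{sorted(missing)}")
    out = []
    for sample, grp in frame.groupby("sample", sort=True):
        loci = {str(locus): sorted(set(sub["allele"].astype(str)))
                for locus, sub in grp.groupby("locus")}
        out.append(MicrosatGenotype(sample_id=str(sample), loci=loci))
    return out


def write_microsat(genotypes: list[MicrosatGenotype], path) -> None:
    rows = [{"sample": g.sample_id, "locus": locus, "allele": allele}
            for g in genotypes
            for locus, alleles in sorted(g.loci.items())
            for allele in alleles]
    pd.DataFrame(rows, columns=["sample", "locus", "allele"]).to_csv(
        path, index=False)


# -- VCF ------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=coralfront-synth
##contig=<ID={contig},length={length}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(records: pd.DataFrame, path, sample_id: str) -> None:
    """Write one sample's variant records as an uncompressed VCF v4.2.

    ``records`` columns: ``chrom, pos, ref, alts`` (comma-joined) and
    ``genotype`` (e.g. ``0/1/2/2``).
    """
    recs = records.sort_values(["chrom", "pos"])
    contig = recs["chrom"].iloc[0] if len(recs) else "contig1"
    length = int(recs["pos"].max()) + 1000 if len(recs) else 1000
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contig=contig, length=length))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample_id}\n")
        for _, r in recs.iterrows():
            fh.write(f"{r['chrom']}\t{int(r['pos'])}\t.\t{r['ref']}\t"
                     f"{r['alts']}\t100\tPASS\t.\tGT\t{r['genotype']}\n")


def write_variant_tables(records: pd.DataFrame, directory) -> dict[str, Path]:
    """Write one single-sample VCF per colony (per-sample variant calling).

    Returns sample_id -> path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sample_id, grp in records.groupby("sample_id", sort=True):
        path = directory / f"{sample_id}.vcf"
        write_vcf(grp, path, sample_id=str(sample_id))
        paths[str(sample_id)] = path
    return paths
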