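"""OTU-table filtering and diversity analysis for 16S/ITS2 metabarcoding.

Operates from the OTU table onward (read processing, clustering and
taxonomic affiliation happen upstream): abundance filtering, alpha
diversity (observed richness, bias-corrected Chao1, Shannon), Bray-Curtis
beta diversity with principal coordinate analysis, and per-index ANOVA
across the entity x depth groups with BH correction across indices.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "filter_otu_table",
    "alpha_diversity",
    "bray_curtis_matrix",
    "pcoa",
    "test_alpha_diversity",
]


def filter_otu_table(table: pd.DataFrame, min_fraction: float = 0.01,
                     drop_singletons: bool = True) -> pd.DataFrame:
    """Drop rare OTUs from an OTUs x samples count table.

    OTUs whose total count is below ``min_fraction`` of the grand total
    are removed (the 1% sequence-tag filter), and singletons (total count
    of exactly 1, typically sequencing artifacts) when flagged.
    """
    if not 0 <= min_fraction < 1:
        raise ValueError("min_fraction must be in [0, 1)")
    if (table.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    totals = table.sum(axis=1)
    grand = totals.sum()
    keep = pd.Series(True, index=table.index)
    if grand > 0 and min_fraction > 0:
        keep &= totals / grand >= min_fraction
    if drop_singletons:
        keep &= totals != 1
    out = table.loc[keep]
    if out.empty:
        logger.warning("OTU table is empty after filtering")
    out.attrs["n_removed"] = int((~keep).sum())
    return out


def alpha_diversity(table: pd.DataFrame, shannon_base: float = np.e
                    ) -> pd.DataFrame:
    """Observed richness, bias-corrected Chao1 and Shannon per sample.

    Chao1 uses the bias-corrected form ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))``
    with ``F1``/``F2`` the singleton/doubleton counts (defined even when no
    doubletons exist, and equal to ``S_obs`` when ``F1 = 0``).  Shannon is
    ``-sum p_i log p_i`` over non-zero proportions, natural log by default.
    """
    mat = table.to_numpy(dtype=float)
    if (mat.sum(axis=0) <= 0).any():
        bad = table.columns[mat.sum(axis=0) <= 0].tolist()
        raise ValueError(f"zero-total samples: {bad}")
    rows = []
    for j, sample in enumerate(table.columns):
        x = mat[:, j]
        observed = int((x > 0).sum())
        f1 = int((x == 1).sum())
        f2 = int((x == 2).sum())
        chao1 = observed + f1 * (f1 - 1) / (2.0 * (f2 + 1))
        p = x[x > 0] / x.sum()
        shannon = float(-(p * np.log(p)).sum() / np.log(shannon_base))
        rows.append({"sample_id": sample, "observed": observed,
                     "chao1": chao1, "shannon": shannon})
    return pd.DataFrame(rows).set_index("sample_id")


def bray_curtis_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between samples.

    ``BC(x, y) = 1 - 2 sum_i min(x_i, y_i) / (sum x + sum y)`` on raw
    counts (the statistic is deliberately sensitive to library size, as
    used here).  A pair of all-zero samples has no defined dissimilarity
    and is reported as NaN with a warning.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    mat = table.to_numpy(dtype=float)
    n = mat.shape[1]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = mat[:, i].sum() + mat[:, j].sum()
            if denom == 0:
                logger.warning("both samples all-zero: %s, %s",
                               table.columns[i], table.columns[j])
                bc = np.nan
            else:
                bc = 1.0 - 2.0 * np.minimum(mat[:, i], mat[:, j]).sum() / denom
            out[i, j] = out[j, i] = bc
    return pd.DataFrame(out, index=table.columns, columns=table.columns)


def pcoa(dissimilarity: pd.DataFrame) -> dict:
    """Classical (metric) multidimensional scaling of a dissimilarity matrix.

    Double-centers ``-D^2 / 2`` and eigendecomposes; axes are ordered by
    decreasing eigenvalue and axes with negative eigenvalues (the signature
    of a non-Euclidean input) are dropped with a logged count.  For a
    Euclidean-embeddable input the coordinates reproduce the distances
    exactly.
    """
    d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10, equal_nan=True):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-9 * max(abs(eigval).max(), 1.0)
    positive = eigval > tol
    n_negative = int((eigval < -tol).sum())
    if n_negative:
        logger.info("dropping %d negative-eigenvalue axes "
                    "(non-Euclidean input)", n_negative)
    coords = eigvec[:, positive] * np.sqrt(eigval[positive])
    index = (dissimilarity.index if isinstance(dissimilarity, pd.DataFrame)
             else pd.RangeIndex(n))
    frame = pd.DataFrame(coords, index=index,
                         columns=[f"PCo{i+1}" for i in range(coords.shape[1])])
    return {"coordinates": frame, "eigenvalues": eigval,
            "n_negative": n_negative,
            "proportion_explained": (eigval[positive] / eigval[positive].sum()
                                     if positive.any() else eigval[positive])}


def test_alpha_diversity(report: pd.DataFrame, metadata: pd.DataFrame,
                         indices: tuple = ("observed", "chao1", "shannon")
                         ) -> pd.DataFrame:
    """One-way ANOVA of each alpha-diversity index across entity x depth.

    Samples are grouped by the combination of entity and depth (four
    groups in the full design); the per-index p-values are BH-adjusted
    across the tested indices.  Every group needs >= 2 samples.
    """
    meta = metadata.set_index("sample_id").loc[list(report.index)]
    grouping = meta["entity"].astype(str) + "/" + meta["depth"].astype(str)
    groups = sorted(grouping.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for idx in indices:
        arrays = [report.loc[grouping == g, idx].to_numpy(dtype=float)
                  for g in groups]
        if any(a.size < 2 for a in arrays):
            raise ValueError("every group needs >= 2 samples")
        if all(np.ptp(np.concatenate(arrays)) == 0 for _ in (0,)):
            f, p = 0.0, 1.0
        else:
            f, p = stats.f_oneway(*arrays)
        rows.append({"index": idx, "F": float(f), "pvalue": float(p)})
    out = pd.DataFrame(rows).set_index("index")
    out["fdr"] = bh_adjust(out["pvalue"].to_numpy(dtype=float))
    out.attrs["groups"] = groups
    return out
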