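"""Frontloading classification and DAPC-based transcriptomic plasticity.

Two complementary views of how chimeric colonies differ from non-chimeric
ones in their stress response:

* **Gene-level classification.**  Starting from the genes that respond to
  the depth translocation in *non-chimeras*, each gene is asked how it
  behaves in chimeras: constitutively elevated at the acclimation depth
  (frontloaded), responding more strongly in the same direction (higher
  plasticity), both, or neither.
* **Transcriptome-level plasticity.**  A discriminant analysis of
  principal components (DAPC) is trained on the non-chimera samples with
  depth as the predefined grouping, then the chimera samples are projected
  onto the single discriminant axis.  The displacement between a group's
  control and stressed coordinates measures its transcriptomic plasticity;
  reduced displacement with wider spread is the robustness signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "classify_frontloading",
    "DAPCModel",
    "fit_dapc",
    "project_dapc",
    "plasticity_metrics",
]

CATEGORIES = ("FRONTLOADED", "HIGHER_PLASTICITY",
              "FRONTLOADED_AND_HIGHER_PLASTICITY", "UNCLASSIFIED")


def classify_frontloading(responsive: pd.DataFrame, basal: pd.DataFrame,
                          chimera_response: pd.DataFrame,
                          alpha: float = 0.05,
                          require_basal_significance: bool = True,
                          require_magnitude: bool = True,
                          require_sign_concordance: bool = True
                          ) -> pd.DataFrame:
    """Classify stress-responsive genes by their behaviour in chimeras.

    Parameters
    ----------
    responsive
        DE table for the depth response in non-chimeras (2m vs 10m); only
        genes with ``fdr < alpha`` here enter the classification.
    basal
        DE table for chimera vs non-chimera at the acclimation depth
        (10m); positive log2fc means higher basal expression in chimeras.
    chimera_response
        DE table for the depth response in chimeras (2m vs 10m).
    alpha
        FDR threshold applied to all three contrasts.
    require_basal_significance, require_magnitude, require_sign_concordance
        Individually switchable parts of the rule, on by default:
        the frontloaded call requires ``basal.fdr < alpha`` (not just a
        positive estimate); the higher-plasticity call requires the
        chimera response to exceed the non-chimera response in magnitude
        and to share its sign (an opposite-direction response is not
        amplified plasticity).

    Returns one row per entering gene with the category and the log2fc/fdr
    of the three contrasts.  Categories are mutually exclusive and
    exhaustive over the entering set: FRONTLOADED (higher basal, no
    amplified response), HIGHER_PLASTICITY (amplified same-direction
    response without elevated basal expression),
    FRONTLOADED_AND_HIGHER_PLASTICITY, or UNCLASSIFIED.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    entering = responsive.index[responsive["fdr"] < alpha]
    for name, table in (("basal", basal), ("chimera_response", chimera_response)):
        missing = entering.difference(table.index)
        if len(missing):
            raise ValueError(f"genes absent from the {name} table: "
                             f"{list(missing[:10])}")
    rows = []
    for gene in entering:
        r_lfc = responsive.at[gene, "log2fc"]
        b_lfc = basal.at[gene, "log2fc"]
        b_fdr = basal.at[gene, "fdr"]
        c_lfc = chimera_response.at[gene, "log2fc"]
        c_fdr = chimera_response.at[gene, "fdr"]

        basal_sig = bool(np.isfinite(b_fdr) and b_fdr < alpha)
        frontloaded = (basal_sig or not require_basal_significance) \
            and np.isfinite(b_lfc) and b_lfc > 0

        chim_sig = bool(np.isfinite(c_fdr) and c_fdr < alpha)
        plasticity = chim_sig
        if plasticity and require_magnitude:
            plasticity = np.isfinite(c_lfc) and abs(c_lfc) > abs(r_lfc)
        if plasticity and require_sign_concordance:
            plasticity = np.sign(c_lfc) == np.sign(r_lfc)

        if frontloaded and plasticity:
            category = "FRONTLOADED_AND_HIGHER_PLASTICITY"
        elif frontloaded:
            category = "FRONTLOADED"
        elif plasticity:
            # with the frontloaded flag false, basal expression is either
            # not elevated or not credibly so; both read as "identical or
            # lower basal expression"
            if (not basal_sig) or b_lfc <= 0:
                category = "HIGHER_PLASTICITY"
            else:
                category = "UNCLASSIFIED"
        else:
            category = "UNCLASSIFIED"
        rows.append({
            "gene_id": gene, "category": category,
            "responsive_log2fc": r_lfc,
            "responsive_fdr": responsive.at[gene, "fdr"],
            "basal_log2fc": b_lfc, "basal_fdr": b_fdr,
            "chimera_log2fc": c_lfc, "chimera_fdr": c_fdr,
        })
    out = pd.DataFrame(rows, columns=[
        "gene_id", "category", "responsive_log2fc", "responsive_fdr",
        "basal_log2fc", "basal_fdr", "chimera_log2fc", "chimera_fdr"])
    if len(out):
        out = out.set_index("gene_id")
    out.attrs["alpha"] = alpha
    return out


@dataclass
class DAPCModel:
    """Everything needed to project new samples onto the discriminant axis.

    ``loadings`` are orthonormal principal-axis loadings (genes x n_pcs);
    ``discriminant`` maps retained PC scores to the single discriminant
    coordinate, scaled so the pooled within-group variance of the training
    coordinates is 1.
    """

    gene_ids: tuple
    center: np.ndarray
    loadings: np.ndarray
    discriminant: np.ndarray
    explained_variance: np.ndarray
    groups: tuple
    group_means: dict
    training_coords: pd.Series

    @property
    def n_pcs(self) -> int:
        return self.loadings.shape[1]

    def gene_loadings(self) -> pd.Series:
        """Discriminant direction expressed in gene space."""
        return pd.Series(self.loadings @ self.discriminant,
                         index=list(self.gene_ids))


def _choose_n_pcs(explained: np.ndarray, n_train: int,
                  n_pcs: int | float | None) -> int:
    rank = explained.size
    if n_pcs is None:
        n_pcs = 0.8
    if isinstance(n_pcs, float):
        if not 0 < n_pcs <= 1:
            raise ValueError("variance fraction must be in (0, 1]")
        k = int(np.searchsorted(np.cumsum(explained), n_pcs - 1e-12) + 1)
        k = min(k, max(n_train - 3, 1))
    else:
        k = int(n_pcs)
    if k < 1:
        raise ValueError("need at least one principal component")
    if k > rank:
        raise ValueError(f"n_pcs={k} exceeds the data rank {rank}")
    if k > n_train - 2:
        raise ValueError(f"n_pcs={k} too large for {n_train} training "
                         "samples (need n_pcs <= n_train - 2)")
    return k


def fit_dapc(adjusted: pd.DataFrame, groups: pd.Series,
             n_pcs: int | float | None = None) -> DAPCModel:
    """Fit a two-group DAPC: PCA by SVD, then LDA on retained PC scores.

    Parameters
    ----------
    adjusted
        Genes x samples adjusted log expression of the training samples.
    groups
        Sample -> group label; exactly two levels, each with >= 2 samples.
    n_pcs
        Number of PCs to retain, or a variance fraction; default keeps the
        smallest number of PCs explaining >= 80% of variance, capped at
        ``n_train - 3``.

    The discriminant direction is ``pinv(Sw) (m1 - m2)`` on PC scores with
    the pooled within-group covariance ``Sw``; its sign is fixed by making
    the largest-magnitude gene loading positive, and its scale by unit
    pooled within-group variance of the training coordinates.
    """
    g = groups.reindex(adjusted.columns)
    if g.isna().any():
        raise ValueError("group labels missing for some training samples")
    levels = tuple(sorted(g.unique()))
    if len(levels) != 2:
        raise ValueError(f"DAPC here is two-group; got levels {levels}")
    counts = g.value_counts()
    if (counts < 2).any():
        raise ValueError(f"every group needs >= 2 samples; got {dict(counts)}")

    X = adjusted.to_numpy(dtype=float).T            # samples x genes
    n_train = X.shape[0]
    center = X.mean(axis=0)
    Xc = X - center
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    keep = s > 1e-12 * s.max()
    u, s, vt = u[:, keep], s[keep], vt[keep]
    var = s ** 2
    explained = var / var.sum()
    k = _choose_n_pcs(explained, n_train, n_pcs)
    scores = u[:, :k] * s[:k]                        # samples x k
    loadings = vt[:k].T                              # genes x k

    masks = {lev: (g == lev).to_numpy() for lev in levels}
    means = {lev: scores[m].mean(axis=0) for lev, m in masks.items()}
    sw = np.zeros((k, k))
    for lev, m in masks.items():
        d = scores[m] - means[lev]
        sw += d.T @ d
    sw /= (n_train - 2)
    w = np.linalg.pinv(sw) @ (means[levels[0]] - means[levels[1]])
    within_var = float(w @ sw @ w)
    if within_var > 0:
        w = w / np.sqrt(within_var)
    gene_dir = loadings @ w
    sign = np.sign(gene_dir[np.argmax(np.abs(gene_dir))])
    if sign < 0:
        w = -w
    coords = scores @ w
    model = DAPCModel(
        gene_ids=tuple(adjusted.index), center=center, loadings=loadings,
        discriminant=w, explained_variance=explained[:k], groups=levels,
        group_means={lev: float(coords[m].mean()) for lev, m in masks.items()},
        training_coords=pd.Series(coords, index=adjusted.columns),
    )
    return model


def project_dapc(model: DAPCModel, new: pd.DataFrame) -> pd.Series:
    """Project new samples (genes x samples) onto the discriminant axis."""
    if tuple(new.index) != model.gene_ids:
        if set(new.index) != set(model.gene_ids):
            raise ValueError("gene universe differs from the fitted model")
        new = new.reindex(list(model.gene_ids))
    X = new.to_numpy(dtype=float).T - model.center
    coords = (X @ model.loadings) @ model.discriminant
    return pd.Series(coords, index=new.columns, name="dapc_coord")


def _range_overlap(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric range-overlap fraction of two coordinate samples."""
    in_b = np.mean((a >= b.min()) & (a <= b.max()))
    in_a = np.mean((b >= a.min()) & (b <= a.max()))
    return float((in_b + in_a) / 2.0)


def plasticity_metrics(coords: pd.DataFrame, control: str = "10m",
                       stressed: str = "2m") -> dict:
    """Per-entity plasticity summaries on the discriminant axis.

    ``coords`` has columns ``coord, entity, depth``.  For each entity:
    *shift* is the absolute difference between the mean coordinate of the
    stressed and control conditions (transcriptomic plasticity); *overlap*
    the symmetric fraction of each condition's coordinates falling inside
    the other's range (1 = indistinguishable conditions); *diversity* the
    within-condition pooled coordinate variance (transcriptomic
    diversity).  The comparison block contrasts chimera vs non-chimera.
    """
    required = {"coord", "entity", "depth"}
    if not required <= set(coords.columns):
        raise ValueError(f"coords needs columns {sorted(required)}")
    out: dict = {"per_entity": {}, "control": control, "stressed": stressed}
    for entity, grp in coords.groupby("entity", sort=True):
        a = grp.loc[grp["depth"] == control, "coord"].to_numpy(dtype=float)
        b = grp.loc[grp["depth"] == stressed, "coord"].to_numpy(dtype=float)
        if a.size == 0 or b.size == 0:
            raise ValueError(f"entity {entity!r} lacks samples in one depth")
        pooled_num = 0.0
        pooled_den = 0
        for arr in (a, b):
            if arr.size > 1:
                pooled_num += arr.var(ddof=1) * (arr.size - 1)
                pooled_den += arr.size - 1
        out["per_entity"][str(entity)] = {
            "shift": float(abs(b.mean() - a.mean())),
            "overlap": _range_overlap(a, b),
            "diversity": float(pooled_num / pooled_den) if pooled_den else 0.0,
            "n_control": int(a.size), "n_stressed": int(b.size),
        }
    ents = out["per_entity"]
    if {"chimera", "nonchimera"} <= set(ents):
        out["comparison"] = {
            "shift_ratio_chimera_over_nonchimera":
                ents["chimera"]["shift"] / ents["nonchimera"]["shift"]
                if ents["nonchimera"]["shift"] else np.inf,
            "chimera_less_plastic":
                bool(ents["chimera"]["shift"] < ents["nonchimera"]["shift"]),
            "chimera_more_diverse":
                bool(ents["chimera"]["diversity"] > ents["nonchimera"]["diversity"]),
        }
    return out
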