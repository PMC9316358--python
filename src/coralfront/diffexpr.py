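"""Negative-binomial differential expression with a mother-colony covariate.

A deliberately small NB-GLM engine in the DESeq2 tradition: median-of-ratios
size factors, per-gene method-of-moments dispersions shrunk toward a
mean-dispersion trend, and a Wald test on the contrast coefficient of a
log-linear model ``log mu = X beta + log s``.  The design matrix carries the
treatment factor of interest plus mother-colony (batch) indicator columns,
because colonies descend from seven mother colonies whose brood effects
would otherwise masquerade as treatment effects.

It is not a DESeq2 port: there is no outlier (Cook's) filtering, no
independent filtering and no fold-change shrinkage.  Downstream conclusions
here depend on contrasts and FDR thresholds, not on those refinements.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "estimate_size_factors",
    "rlog_like",
    "estimate_dispersions",
    "build_design",
    "wald_nb_test",
    "bh_adjust",
    "remove_batch_effect",
    "sample_ordination",
]

_DISPERSION_FLOOR = 1e-8
_LN2 = np.log(2.0)


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample normalization factors.

    For every gene with strictly positive counts in all samples, compute
    the ratio of each sample's count to the gene's geometric mean across
    samples; the sample's size factor is the median of these ratios.
    Zero-containing genes never enter the reference, so adding such a gene
    leaves the factors unchanged.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample; "
                         "cannot form the median-of-ratios reference")
    ref = mat[positive]
    log_geo = np.log(ref).mean(axis=1, keepdims=True)
    ratios = ref / np.exp(log_geo)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def rlog_like(counts: pd.DataFrame, size_factors: pd.Series | None = None
              ) -> pd.DataFrame:
    """Variance-damped log transform: ``log2(count / size_factor + 1)``.

    A monotone stand-in for regularized-log transforms, used for
    ordination, batch removal and DAPC where only relative geometry
    matters.
    """
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    sf = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    return pd.DataFrame(np.log2(counts.to_numpy(dtype=float) / sf + 1.0),
                        index=counts.index, columns=counts.columns)


def estimate_dispersions(counts: pd.DataFrame,
                         size_factors: pd.Series | None = None,
                         design: np.ndarray | None = None,
                         shrink_weight: float = 0.7) -> pd.DataFrame:
    """Per-gene NB dispersion by moments, shrunk toward a fitted trend.

    On normalized counts ``q = K/s`` the NB model implies
    ``Var(q) ~= mu * mean(1/s) + alpha * mu^2``, giving the raw estimate
    ``alpha_hat = (var - mu * mean(1/s)) / mu^2``.  When a design matrix
    is supplied the variance is the residual mean square after projecting
    each gene's normalized counts onto the design (so treatment and
    mother-colony effects do not masquerade as biological dispersion);
    otherwise the plain across-sample variance is used.  Raw estimates are
    noisy at a handful of replicates, so they are averaged with a trend
    ``a1 / mu + a0`` fitted across genes (``shrink_weight`` is the trend's
    weight).  All-zero genes receive the floor value and are flagged.

    Returns a data frame with columns ``dispersion`` and ``all_zero``.
    """
    if not 0 <= shrink_weight <= 1:
        raise ValueError("shrink_weight must be in [0, 1]")
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    sf = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    q = counts.to_numpy(dtype=float) / sf
    n = q.shape[1]
    if n < 2:
        raise ValueError("need at least 2 samples")
    mu = q.mean(axis=1)
    all_zero = mu == 0
    if design is not None:
        X = np.asarray(design, dtype=float)
        df_resid = n - np.linalg.matrix_rank(X)
        if df_resid < 2:
            raise ValueError("need at least 2 residual degrees of freedom")
        hat = X @ np.linalg.pinv(X)
        leverage = np.diag(hat)
        fitted = np.clip(q @ hat.T, 0.0, None)
        resid = q - q @ hat.T
        # second moments around the fitted means, with the df correction
        # for the variance soaked up by the projection
        rss = (resid ** 2).sum(axis=1) * (n / df_resid)
        poisson_part = (fitted / sf).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            num = rss - poisson_part
            # E[fitted^2] exceeds mu^2 by leverage * Var; correct the
            # denominator with a first-pass dispersion estimate
            den0 = (fitted ** 2).sum(axis=1)
            alpha1 = np.clip(num / den0, 0.0, None)
            correction = (leverage * (fitted / sf
                                      + alpha1[:, None] * fitted ** 2)
                          ).sum(axis=1)
            denom = np.maximum(den0 - correction, 0.5 * den0)
            raw = num / np.clip(denom, 1e-12, None)
    else:
        var = q.var(axis=1, ddof=1)
        xim = float((1.0 / sf).mean())
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = (var - mu * xim) / mu ** 2
    raw = np.where(all_zero, _DISPERSION_FLOOR, raw)
    raw = np.clip(raw, _DISPERSION_FLOOR, None)

    # trend a1/mu + a0 on genes with informative raw estimates
    use = (~all_zero) & (raw > _DISPERSION_FLOOR)
    if use.sum() >= 10:
        A = np.column_stack([1.0 / mu[use], np.ones(use.sum())])
        coef, *_ = np.linalg.lstsq(A, raw[use], rcond=None)
        a1, a0 = np.clip(coef, 0.0, None)
    else:   # too few genes to fit a trend; fall back to the raw median
        a1, a0 = 0.0, float(np.median(raw[~all_zero])) if (~all_zero).any() else 0.0
    with np.errstate(divide="ignore"):
        trend = np.where(all_zero, _DISPERSION_FLOOR, a1 / np.maximum(mu, 1e-12) + a0)
    disp = (1.0 - shrink_weight) * raw + shrink_weight * trend
    disp = np.clip(disp, _DISPERSION_FLOOR, None)
    disp[all_zero] = _DISPERSION_FLOOR
    return pd.DataFrame({"dispersion": disp, "all_zero": all_zero},
                        index=counts.index)


def build_design(metadata: pd.DataFrame, factor: str, level_num: str,
                 level_den: str, covariates: tuple = ("mother_colony",)
                 ) -> tuple[np.ndarray, list[str], int]:
    """Design matrix for a two-level contrast plus covariate indicators.

    Columns: intercept, an indicator that is 1 for ``level_num`` samples
    (so a positive coefficient means higher in ``level_num`` than in
    ``level_den``), and treatment-coded dummies for each covariate level
    beyond the first.  Raises on rank deficiency, naming the aliased
    columns (e.g., a mother colony perfectly confounded with treatment).
    """
    fac = metadata[factor]
    bad = set(fac.unique()) - {level_num, level_den}
    if bad:
        raise ValueError(f"samples outside contrast levels present: {sorted(bad)}")
    cols = [np.ones(len(metadata)), (fac == level_num).to_numpy(dtype=float)]
    names = ["intercept", f"{factor}[{level_num}.vs.{level_den}]"]
    for cov in covariates:
        levels = sorted(metadata[cov].unique())
        for lev in levels[1:]:
            cols.append((metadata[cov] == lev).to_numpy(dtype=float))
            names.append(f"{cov}[{lev}]")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns via pivoted QR
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        aliased = [names[i] for i in range(len(names))
                   if i < diag.size and diag[i] < 1e-10 * diag.max()]
        raise ValueError(f"design matrix is rank deficient (rank {rank} < "
                         f"{X.shape[1]}); aliased columns: {aliased or 'unknown'}")
    return X, names, 1   # contrast coefficient is column 1


def _irls_nb(y: np.ndarray, X: np.ndarray, offset: np.ndarray,
             alpha: np.ndarray, max_iter: int = 50, tol: float = 1e-8
             ) -> tuple[np.ndarray, np.ndarray]:
    """Batched IRLS for NB log-linear models sharing one design matrix.

    ``y`` is genes x samples, ``alpha`` the per-gene dispersion.  Returns
    (beta, covariance) stacked over genes.  The working weights are
    ``mu / (1 + alpha mu)`` (canonical log link, fixed dispersion).
    """
    n_genes, n_samples = y.shape
    p = X.shape[1]
    # initialise from OLS on shifted log counts
    z0 = np.log(y + 0.5) - offset
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T                               # genes x p
    eye = np.eye(p) * 1e-10
    for _ in range(max_iter):
        eta = beta @ X.T + offset               # genes x samples
        eta = np.clip(eta, -50, 50)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = eta - offset + (y - mu) / np.maximum(mu, 1e-300)
        xtwx = np.einsum("jp,gj,jq->gpq", X, w, X, optimize=True) + eye
        xtwz = np.einsum("jp,gj,gj->gp", X, w, z, optimize=True)
        new_beta = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        delta = np.abs(new_beta - beta).max()
        beta = new_beta
        if delta < tol:
            break
    eta = np.clip(beta @ X.T + offset, -50, 50)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha[:, None] * mu)
    xtwx = np.einsum("jp,gj,jq->gpq", X, w, X, optimize=True) + eye
    cov = np.linalg.inv(xtwx)
    return beta, cov


def wald_nb_test(counts: pd.DataFrame, metadata: pd.DataFrame,
                 contrast: tuple[str, str, str],
                 covariates: tuple = ("mother_colony",),
                 size_factors: pd.Series | None = None,
                 dispersions: pd.Series | None = None,
                 df_reference: str = "normal") -> pd.DataFrame:
    """Per-gene Wald test of a two-level contrast in an NB log-linear model.

    Parameters
    ----------
    counts
        Genes x samples integer counts, already subset to the samples of
        the contrast.
    metadata
        One row per sample (``sample_id`` column), aligned with counts.
    contrast
        ``(factor, level_num, level_den)``; positive log2fc means higher
        in ``level_num``.
    covariates
        Metadata columns added as indicator covariates (mother colony by
        default).  Covariates whose levels are absent from the subset are
        dropped automatically.
    df_reference
        ``"normal"`` (default) refers the Wald statistic to the asymptotic
        normal; with trend-shrunk dispersions this is well calibrated at a
        handful of replicates.  ``"t"`` uses a Student t with residual
        degrees of freedom, a deliberately conservative alternative.

    Returns a frame indexed by gene with columns ``base_mean, log2fc, se,
    stat, pvalue, fdr``.  Genes with zero counts in every subset sample are
    untestable; they are kept as NaN rows (their number is logged) and are
    excluded from the BH adjustment.
    """
    meta = metadata.set_index("sample_id").loc[list(counts.columns)].reset_index()
    factor, level_num, level_den = contrast
    X, names, c_idx = build_design(meta, factor, level_num, level_den,
                                   covariates=covariates)
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    sf = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    if dispersions is None:
        dispersions = estimate_dispersions(counts, size_factors,
                                           design=X)["dispersion"]
    alpha = dispersions.reindex(counts.index).to_numpy(dtype=float)

    y = counts.to_numpy(dtype=float)
    testable = y.sum(axis=1) > 0
    n_dropped = int((~testable).sum())
    if n_dropped:
        logger.info("%d all-zero genes untestable in contrast %s",
                    n_dropped, contrast)
    offset = np.log(sf)
    beta, cov = _irls_nb(y[testable], X, offset, alpha[testable])
    b = beta[:, c_idx]
    se_ln = np.sqrt(np.maximum(cov[:, c_idx, c_idx], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = b / se_ln
    df_resid = y.shape[1] - X.shape[1]
    if df_reference == "t":
        if df_resid < 1:
            raise ValueError("no residual degrees of freedom for the t reference")
        pvals = 2.0 * stats.t.sf(np.abs(stat), df=df_resid)
    elif df_reference == "normal":
        pvals = 2.0 * stats.norm.sf(np.abs(stat))
    else:
        raise ValueError("df_reference must be 't' or 'normal'")

    out = pd.DataFrame(index=counts.index,
                       columns=["base_mean", "log2fc", "se", "stat",
                                "pvalue", "fdr"], dtype=float)
    out.loc[testable, "base_mean"] = (y[testable] / sf).mean(axis=1)
    out.loc[testable, "log2fc"] = b / _LN2
    out.loc[testable, "se"] = se_ln / _LN2
    out.loc[testable, "stat"] = stat
    out.loc[testable, "pvalue"] = pvals
    out["fdr"] = bh_adjust(out["pvalue"].to_numpy(dtype=float))
    out.attrs["contrast"] = f"{factor}: {level_num} vs {level_den} " \
                            "(log2fc > 0 means higher in the first level)"
    out.attrs["n_untestable"] = n_dropped
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved).

    NaN entries are ignored for the adjustment and returned as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    q = p[ok]
    if ((q < 0) | (q > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = q.size
    if m == 0:
        return out
    order = np.argsort(q, kind="mergesort")
    ranked = q[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


def remove_batch_effect(log_counts: pd.DataFrame, batch: pd.Series,
                        design: pd.DataFrame | None = None) -> pd.DataFrame:
    """Subtract additive batch (mother-colony) effects from log expression.

    Per gene, a linear model with the retained design columns plus
    sum-contrast batch columns is fitted and only the fitted batch
    component is subtracted — the limma ``removeBatchEffect`` recipe.  With
    sum contrasts, pure additive batch offsets are equalized to the grand
    mean while retained-design effects are untouched.
    """
    samples = list(log_counts.columns)
    b = batch.reindex(samples)
    if b.isna().any():
        raise ValueError("batch labels missing for some samples")
    levels = sorted(b.unique())
    if len(levels) == 1:
        return log_counts.copy()
    B = np.zeros((len(samples), len(levels) - 1))
    for i, lev in enumerate(levels[:-1]):
        B[(b == lev).to_numpy(), i] = 1.0
        B[(b == levels[-1]).to_numpy(), i] = -1.0
    D = np.ones((len(samples), 1))
    if design is not None:
        D = np.column_stack([D, np.asarray(design, dtype=float)])
    M = np.column_stack([D, B])
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise ValueError("batch is confounded with the retained design")
    Y = log_counts.to_numpy(dtype=float).T        # samples x genes
    coef, *_ = np.linalg.lstsq(M, Y, rcond=None)
    batch_part = B @ coef[D.shape[1]:, :]
    return pd.DataFrame((Y - batch_part).T, index=log_counts.index,
                        columns=log_counts.columns)


def sample_ordination(adjusted: pd.DataFrame) -> dict:
    """Distance matrix, average-linkage dendrogram and PCA of samples.

    Euclidean distances on adjusted log expression; PCA by SVD of the
    gene-centered sample matrix.  Explained-variance fractions are over all
    non-null components and sum to 1.
    """
    if adjusted.shape[1] < 3:
        raise ValueError("ordination needs at least 3 samples")
    X = adjusted.to_numpy(dtype=float).T          # samples x genes
    dist_condensed = pdist(X, metric="euclidean")
    dist = pd.DataFrame(squareform(dist_condensed),
                        index=adjusted.columns, columns=adjusted.columns)
    Z = linkage(dist_condensed, method="average")
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    keep = s > 1e-12 * (s.max() if s.size else 1.0)
    coords = u[:, keep] * s[keep]
    var = s[keep] ** 2
    explained = var / var.sum() if var.sum() > 0 else var
    pcs = pd.DataFrame(coords, index=adjusted.columns,
                       columns=[f"PC{i+1}" for i in range(coords.shape[1])])
    return {"distance": dist, "linkage": Z, "coordinates": pcs,
            "explained_variance": explained}
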