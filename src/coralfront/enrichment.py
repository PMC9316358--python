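"""Rank-based GO enrichment with adaptive category clustering.

The GO_MWU approach: instead of testing a hard significance cutoff, every
gene carries a continuous measure (here the log2 fold change of a
contrast) and each GO category is tested for a rank shift of its member
genes against all non-members with a Mann-Whitney U test.  The category
effect size is the *delta-rank*: mean rank of members minus mean rank of
non-members, positive when the category sits toward high values.  Because
GO terms are heavily redundant, near-duplicate categories are first merged
by hierarchical clustering on a set-overlap dissimilarity.  A Fisher exact
mode handles binary gene sets (e.g., "is frontloaded").

Delta-ranks from two analyses can be correlated across shared categories
to ask whether two responses engage the same processes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .chimerism import mann_whitney_u

logger = logging.getLogger(__name__)

__all__ = [
    "GOAnnotation",
    "GOCategory",
    "GOIndex",
    "build_go_index",
    "cluster_go_terms",
    "mwu_enrichment",
    "fisher_enrichment",
    "delta_rank_correlation",
]

#: GO_MWU-style defaults: drop categories with fewer than 10 genes or more
#: than 10% of the universe; merge clusters tighter than 0.5 dissimilarity.
DEFAULT_SMALLEST = 10
DEFAULT_LARGEST = 0.1
DEFAULT_CUT_HEIGHT = 0.5


@dataclass
class GOAnnotation:
    """Gene-to-term annotation with optional is_a parent links."""

    gene_terms: dict[str, set]
    parents: dict[str, set] = field(default_factory=dict)
    term_names: dict[str, str] = field(default_factory=dict)

    def ancestors(self, term: str) -> set:
        """All ancestor terms of ``term`` (term itself excluded)."""
        seen: set = set()
        stack = list(self.parents.get(term, ()))
        path = {term}
        while stack:
            t = stack.pop()
            if t in path:
                raise ValueError(f"cycle in term parent links at {t!r}")
            if t in seen:
                continue
            seen.add(t)
            stack.extend(self.parents.get(t, ()))
        return seen


@dataclass(frozen=True)
class GOCategory:
    term_ids: tuple
    name: str
    genes: frozenset


@dataclass
class GOIndex:
    categories: list[GOCategory]
    universe: tuple


def build_go_index(annotation: GOAnnotation, universe,
                   smallest: int = DEFAULT_SMALLEST,
                   largest: float = DEFAULT_LARGEST,
                   propagate: bool = True) -> GOIndex:
    """Invert the annotation into filtered per-term gene sets.

    With ``propagate`` and parent links present, each gene's terms are
    closed under ancestors first (a gene annotated to a child belongs to
    the parent too).  Terms with fewer than ``smallest`` member genes in
    the universe, or more than ``largest`` (a fraction) of the universe,
    are dropped.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("empty gene universe")
    if not 0 < largest < 1:
        raise ValueError("largest must be a fraction in (0, 1)")
    uset = set(universe)
    term_genes: dict[str, set] = {}
    cache: dict[str, set] = {}
    for gene, terms in annotation.gene_terms.items():
        if gene not in uset:
            continue
        closed = set(terms)
        if propagate and annotation.parents:
            for t in terms:
                if t not in cache:
                    cache[t] = annotation.ancestors(t)
                closed |= cache[t]
        for t in closed:
            term_genes.setdefault(t, set()).add(gene)
    max_size = largest * len(universe)
    cats = [GOCategory(term_ids=(t,),
                       name=annotation.term_names.get(t, t),
                       genes=frozenset(genes))
            for t, genes in sorted(term_genes.items())
            if smallest <= len(genes) <= max_size]
    if not cats:
        logger.warning("no testable categories after size filtering")
    return GOIndex(categories=cats, universe=tuple(universe))


def _dissimilarity(a: frozenset, b: frozenset, kind: str) -> float:
    inter = len(a & b)
    if kind == "overlap":       # 1 - overlap coefficient (GO_MWU-style)
        return 1.0 - inter / min(len(a), len(b))
    if kind == "jaccard":
        return 1.0 - inter / len(a | b)
    raise ValueError(f"unknown dissimilarity {kind!r}")


def cluster_go_terms(index: GOIndex,
                     cut_height: float = DEFAULT_CUT_HEIGHT,
                     largest: float = DEFAULT_LARGEST,
                     dissimilarity: str = "overlap") -> GOIndex:
    """Merge near-duplicate categories by complete-linkage clustering.

    Pairwise dissimilarity is ``1 - |A n B| / min(|A|, |B|)`` (identical or
    nested sets score 0, disjoint sets 1); clusters whose complete-linkage
    height is at most ``cut_height`` collapse into a single category whose
    gene set is the union and whose name concatenates the member names.
    Merged categories exceeding the ``largest`` fraction of the universe
    are dropped again, so clustering cannot manufacture a mega-category.
    """
    if not 0 <= cut_height <= 1:
        raise ValueError("cut_height must be in [0, 1]")
    cats = index.categories
    if len(cats) <= 1:
        return GOIndex(categories=list(cats), universe=index.universe)
    m = len(cats)
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d[i, j] = d[j, i] = _dissimilarity(cats[i].genes, cats[j].genes,
                                               dissimilarity)
    Z = linkage(squareform(d, checks=False), method="complete")
    labels = fcluster(Z, t=cut_height, criterion="distance")
    merged: list[GOCategory] = []
    max_size = largest * len(index.universe)
    for lab in sorted(set(labels)):
        members = [cats[i] for i in np.flatnonzero(labels == lab)]
        genes = frozenset().union(*(c.genes for c in members))
        if len(genes) > max_size:
            logger.info("dropping merged category of %d genes (> largest)",
                        len(genes))
            continue
        merged.append(GOCategory(
            term_ids=tuple(t for c in members for t in c.term_ids),
            name="; ".join(c.name for c in members),
            genes=genes))
    return GOIndex(categories=merged, universe=index.universe)


def _finalize(rows: list[dict], index: GOIndex) -> pd.DataFrame:
    from .diffexpr import bh_adjust

    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["pvalue"].to_numpy(dtype=float))
    else:
        out = pd.DataFrame(columns=["category", "name", "n", "n_strong",
                                    "effect", "direction", "pvalue", "fdr",
                                    "genes"])
    out.attrs["n_universe"] = len(index.universe)
    return out


def mwu_enrichment(measure: pd.Series, index: GOIndex,
                   strong_cutoff: float = 2.0) -> pd.DataFrame:
    """Mann-Whitney U enrichment of each category on a continuous measure.

    ``measure`` maps every universe gene to a value (log2 fold change).
    Genes are ranked ascending with midranks for ties; each category's
    member ranks are compared against non-member ranks (two-sided,
    tie-corrected normal approximation) and summarized by the delta-rank.
    ``n_strong`` counts members with ``|measure| > strong_cutoff`` — the
    x/y display statistic of the figure legends, never a test input.
    Being rank-based, the result is invariant under any strictly monotone
    transform of the measure.
    """
    missing = [g for g in index.universe if g not in measure.index]
    if missing:
        raise ValueError(f"measure undefined for {len(missing)} universe "
                         f"genes, e.g. {missing[:5]}")
    vals = measure.reindex(list(index.universe)).to_numpy(dtype=float)
    ranks = stats.rankdata(vals)
    pos = {g: i for i, g in enumerate(index.universe)}
    n_total = len(index.universe)
    rows = []
    for cat in index.categories:
        idx = np.fromiter((pos[g] for g in cat.genes if g in pos), dtype=int)
        n_m = idx.size
        if n_m == 0:
            continue
        if n_m == n_total:
            raise ValueError(f"category {cat.name!r} equals the whole "
                             "universe and cannot be tested")
        member = np.zeros(n_total, dtype=bool)
        member[idx] = True
        delta = float(ranks[member].mean() - ranks[~member].mean())
        res = mann_whitney_u(vals[member], vals[~member], mode="normal")
        rows.append({
            "category": "|".join(cat.term_ids), "name": cat.name,
            "n": n_m,
            "n_strong": int((np.abs(vals[member]) > strong_cutoff).sum()),
            "effect": delta, "direction": int(np.sign(delta)),
            "pvalue": res.p_value, "genes": cat.genes,
        })
    return _finalize(rows, index)


def fisher_enrichment(flag: pd.Series, index: GOIndex) -> pd.DataFrame:
    """Fisher exact enrichment of each category in a binary gene set.

    For each category a 2x2 table (member x flagged) is tested two-sided;
    the reported effect is the sample odds ratio.  Raises if the flag is
    constant over the universe (no 2x2 table exists).
    """
    missing = [g for g in index.universe if g not in flag.index]
    if missing:
        raise ValueError(f"flag undefined for {len(missing)} universe genes")
    f = flag.reindex(list(index.universe)).astype(bool).to_numpy()
    n_total = len(index.universe)
    n_flagged = int(f.sum())
    if n_flagged in (0, n_total):
        raise ValueError("flag is constant over the universe")
    pos = {g: i for i, g in enumerate(index.universe)}
    rows = []
    for cat in index.categories:
        idx = np.fromiter((pos[g] for g in cat.genes if g in pos), dtype=int)
        n_m = idx.size
        if n_m == 0:
            continue
        k = int(f[idx].sum())
        table = [[k, n_m - k], [n_flagged - k, n_total - n_m - (n_flagged - k)]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        expected = n_m * n_flagged / n_total
        rows.append({
            "category": "|".join(cat.term_ids), "name": cat.name,
            "n": n_m, "n_strong": k,
            "effect": float(odds), "direction": int(np.sign(k - expected)),
            "pvalue": float(p), "genes": cat.genes,
        })
    return _finalize(rows, index)


def delta_rank_correlation(a: pd.DataFrame, b: pd.DataFrame
                           ) -> tuple[float, pd.DataFrame]:
    """Pearson correlation of delta-ranks across categories shared by two
    enrichment results.

    Categories are matched by member-set identity, falling back to name
    when gene sets are unavailable.  Needs at least 3 shared categories.
    """
    if "genes" in a.columns and "genes" in b.columns:
        key_a = a["genes"].map(frozenset)
        key_b = b["genes"].map(frozenset)
    else:
        key_a, key_b = a["name"], b["name"]
    bmap = {k: v for k, v in zip(key_b, b["effect"])}
    pairs = [(name, ea, bmap[k])
             for k, name, ea in zip(key_a, a["name"], a["effect"])
             if k in bmap]
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} shared categories (need >= 3)")
    table = pd.DataFrame(pairs, columns=["name", "delta_rank_a", "delta_rank_b"])
    r = float(stats.pearsonr(table["delta_rank_a"], table["delta_rank_b"])[0])
    return r, table
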