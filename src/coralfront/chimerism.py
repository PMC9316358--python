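"""Chimerism validation from microsatellites and RNA-seq variant calls.

A coral chimera carries at least two co-occurring genomes, so at some loci
more than the two alleles of a single diploid genotype are observed.  Two
independent lines of evidence are implemented:

* microsatellite genotyping — a colony is called chimeric when at least one
  locus shows more than two distinct alleles;
* multiple nucleotide polymorphisms (MNPs; short multi-base haplotypes) in
  per-sample RNA-seq variant calls — chimeras are expected to carry a
  higher fraction of multiallelic MNP records, which is compared between
  entities with a Mann-Whitney U test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MicrosatGenotype",
    "MNPSummary",
    "RankTestResult",
    "classify_microsat",
    "extract_mnp_summary",
    "mann_whitney_u",
    "test_multiallelic_enrichment",
]

#: "more than two distinct alleles" — a diploid genotype explains at most 2
DEFAULT_ALLELE_THRESHOLD = 2


@dataclass
class MicrosatGenotype:
    """Microsatellite genotype: distinct allele labels per typed locus."""

    sample_id: str
    loci: dict[str, list]

    def distinct_alleles(self) -> dict[str, set]:
        return {locus: set(alleles) for locus, alleles in self.loci.items()}


@dataclass
class MNPSummary:
    """Per-sample MNP tally.

    ``rel_multiallelic`` is the chimerism statistic: the fraction of MNP
    records whose distinct-allele count exceeds ``allele_threshold``.  It is
    reported as 0 with ``undefined=True`` when the sample has no MNPs.
    """

    sample_id: str
    n_mnp: int
    n_multiallelic: int
    rel_multiallelic: float
    allele_threshold: int
    undefined: bool = False
    n_skipped: int = 0


@dataclass
class RankTestResult:
    u_statistic: float
    p_value: float
    method: str                 # "exact" or "normal_approx"
    n1: int
    n2: int
    alternative: str = "two-sided"


def classify_microsat(genotype: MicrosatGenotype,
                      allele_threshold: int = DEFAULT_ALLELE_THRESHOLD
                      ) -> tuple[bool, list[str]]:
    """Call chimeric status from a microsatellite genotype.

    A chimera is identified by at least one locus presenting more than
    ``allele_threshold`` distinct alleles (default more than two, the
    maximum for one diploid genome).  Duplicate allele entries are
    collapsed before counting, so the call is invariant to allele order
    and repetition.
    """
    if not genotype.loci:
        raise ValueError(f"sample {genotype.sample_id}: no typed loci")
    triggering = [locus for locus, alleles in genotype.distinct_alleles().items()
                  if len(alleles) > allele_threshold]
    return bool(triggering), sorted(triggering)


def _is_mnp(ref: str, alts: tuple) -> bool:
    if ref is None or len(ref) < 2 or not alts:
        return False
    for alt in alts:
        if alt is None or not alt.isalpha() or len(alt) != len(ref):
            return False
    return True


def extract_mnp_summary(vcf_path, sample_id: str | None = None,
                        allele_threshold: int = DEFAULT_ALLELE_THRESHOLD
                        ) -> MNPSummary:
    """Tally MNP records and multiallelic MNP records for one sample.

    An MNP record has a REF spanning at least two bases and all ALT alleles
    of the same length as REF (the `bcftools view -v mnps` notion).  The
    distinct-allele count of a record is taken from the sample's genotype
    field when present; for site-only VCFs (per-sample variant calling
    writes one file per colony) it is REF plus all ALTs.  Records that fail
    to parse are skipped and counted.
    """
    import pysam

    vf = pysam.VariantFile(str(vcf_path))
    vcf_samples = list(vf.header.samples)
    use_gt = bool(vcf_samples)
    if use_gt:
        if sample_id is None:
            if len(vcf_samples) > 1:
                raise ValueError("multi-sample VCF: sample_id is required")
            sample_id = vcf_samples[0]
        elif sample_id not in vcf_samples:
            raise ValueError(f"sample {sample_id!r} not in VCF "
                             f"(has {vcf_samples})")
    elif sample_id is None:
        sample_id = str(vcf_path)

    n_mnp = n_multi = n_skipped = 0
    for rec in vf:
        try:
            alts = tuple(rec.alts) if rec.alts else ()
            if not _is_mnp(rec.ref, alts):
                continue
            if use_gt:
                gt = rec.samples[sample_id].get("GT", None)
                called = {a for a in (gt or ()) if a is not None}
                if not called:   # uncalled genotype: all record alleles
                    called = set(range(1 + len(alts)))
            else:
                called = set(range(1 + len(alts)))
            n_mnp += 1
            if len(called) > allele_threshold:
                n_multi += 1
        except (ValueError, KeyError) as exc:   # malformed record
            n_skipped += 1
            logger.warning("skipping malformed record in %s: %s", vcf_path, exc)
    if n_skipped:
        logger.warning("%s: skipped %d malformed records", vcf_path, n_skipped)
    undefined = n_mnp == 0
    rel = 0.0 if undefined else n_multi / n_mnp
    return MNPSummary(sample_id=sample_id, n_mnp=n_mnp, n_multiallelic=n_multi,
                      rel_multiallelic=rel, allele_threshold=allele_threshold,
                      undefined=undefined, n_skipped=n_skipped)


def summarize_variant_frame(records: pd.DataFrame,
                            allele_threshold: int = DEFAULT_ALLELE_THRESHOLD
                            ) -> list[MNPSummary]:
    """MNP summaries from an in-memory record table.

    ``records`` needs columns ``sample_id`` and ``genotype`` (slash-joined
    allele indices); every row is assumed to be an MNP record.  Equivalent
    to writing per-sample VCFs and calling :func:`extract_mnp_summary`,
    without the round trip.
    """
    n_distinct = records["genotype"].map(
        lambda s: len(set(str(s).split("/"))))
    multi = n_distinct > allele_threshold
    out = []
    for sample_id, grp in records.groupby("sample_id", sort=True):
        n_mnp = int(len(grp))
        n_multi = int(multi.loc[grp.index].sum())
        out.append(MNPSummary(
            sample_id=str(sample_id), n_mnp=n_mnp, n_multiallelic=n_multi,
            rel_multiallelic=n_multi / n_mnp if n_mnp else 0.0,
            allele_threshold=allele_threshold, undefined=n_mnp == 0))
    return out


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> tuple:
    """Number of rank arrangements giving each U value (no ties).

    Classic recurrence f(n1, n2, u) = f(n1-1, n2, u-n2) + f(n1, n2-1, u):
    condition on whether the largest observation belongs to sample 1.
    """
    if n1 == 0 or n2 == 0:
        return (1,)
    a = np.asarray(_u_counts(n1 - 1, n2), dtype=float)
    b = np.asarray(_u_counts(n1, n2 - 1), dtype=float)
    out = np.zeros(n1 * n2 + 1)
    out[n2:n2 + a.size] += a
    out[:b.size] += b
    return tuple(out)


def _exact_p(u: float, n1: int, n2: int, alternative: str) -> float:
    counts = np.asarray(_u_counts(n1, n2))
    total = counts.sum()
    cdf = counts.cumsum() / total          # P(U <= k)
    k = int(round(u))
    if alternative == "two-sided":
        lo = min(k, n1 * n2 - k)
        return float(min(1.0, 2.0 * cdf[lo]))
    if alternative == "greater":           # large U of x over y is extreme
        return float(1.0 - (cdf[k - 1] if k > 0 else 0.0))
    if alternative == "less":
        return float(cdf[k])
    raise ValueError(f"unknown alternative {alternative!r}")


def mann_whitney_u(x, y, mode: str = "auto",
                   alternative: str = "two-sided") -> RankTestResult:
    """Mann-Whitney U test.

    ``U = sum over pairs of [x_i > y_j] + 0.5 [x_i == y_j]`` (the statistic
    of the first sample).  The exact null distribution is enumerated by the
    standard recurrence when ``n1 * n2 <= 400`` and there are no ties
    (``mode='auto'``); otherwise a tie-corrected normal approximation with
    continuity correction is used.  ``mode='exact'`` refuses tied data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = (tie_counts > 1).any()
    if mode == "exact" and has_ties:
        raise ValueError("exact mode is undefined with tied observations")
    use_exact = (mode == "exact") or (
        mode == "auto" and not has_ties and n1 * n2 <= 400)
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")

    if use_exact:
        p = _exact_p(u, n1, n2, alternative)
        method = "exact"
    else:
        n = n1 + n2
        tie_term = ((tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
                    if n > 1 else 0.0)
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        mu = n1 * n2 / 2.0
        if sigma2 <= 0:
            p = 1.0
        else:
            sd = np.sqrt(sigma2)
            if alternative == "two-sided":
                z = (abs(u - mu) - 0.5) / sd
                p = float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))
            elif alternative == "greater":
                z = (u - mu - 0.5) / sd
                p = float(stats.norm.sf(z))
            elif alternative == "less":
                z = (u - mu + 0.5) / sd
                p = float(stats.norm.cdf(z))
            else:
                raise ValueError(f"unknown alternative {alternative!r}")
        method = "normal_approx"
    return RankTestResult(u_statistic=float(u), p_value=float(max(p, 0.0)),
                          method=method, n1=n1, n2=n2, alternative=alternative)


def brute_force_mwu_p(x, y, alternative: str = "two-sided") -> float:
    """Independent enumeration oracle for the exact MWU p-value.

    Walks every assignment of the pooled ranks to the two groups and counts
    arrangements at least as extreme as the observed U.  Exponential in the
    pooled size; meant for tiny samples in tests.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size

    def u_of(xs, ys):
        xs = np.asarray(xs)[:, None]
        ys = np.asarray(ys)[None, :]
        return float((xs > ys).sum() + 0.5 * (xs == ys).sum())

    u_obs = u_of(x, y)
    pooled = np.concatenate([x, y])
    idx = range(pooled.size)
    n_extreme = 0
    n_total = 0
    center = n1 * n2 / 2.0
    for combo in itertools.combinations(idx, n1):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(combo)] = True
        u = u_of(pooled[mask], pooled[~mask])
        n_total += 1
        if alternative == "two-sided":
            n_extreme += abs(u - center) >= abs(u_obs - center)
        elif alternative == "greater":
            n_extreme += u >= u_obs
        else:
            n_extreme += u <= u_obs
    return n_extreme / n_total


def test_multiallelic_enrichment(summaries: list[MNPSummary],
                                 metadata: pd.DataFrame,
                                 alternative: str = "two-sided",
                                 mode: str = "auto") -> RankTestResult:
    """Compare the relative multiallelic-MNP load between entities.

    Mann-Whitney U on ``rel_multiallelic``, chimera vs non-chimera.  The
    default is two-sided; ``alternative='greater'`` tests the directional
    hypothesis that chimeras carry the higher load.
    """
    entity = metadata.set_index("sample_id")["entity"]
    missing = [s.sample_id for s in summaries if s.sample_id not in entity.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    chim = [s.rel_multiallelic for s in summaries
            if entity[s.sample_id] == "chimera"]
    nonchim = [s.rel_multiallelic for s in summaries
               if entity[s.sample_id] == "nonchimera"]
    if not chim or not nonchim:
        raise ValueError("both entity groups must be represented")
    return mann_whitney_u(chim, nonchim, mode=mode, alternative=alternative)
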