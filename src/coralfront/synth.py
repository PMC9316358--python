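"""Synthetic data with planted ground truth for every pipeline stage.

The original study measures chimeric and non-chimeric coral colonies at two
depths (acclimated 10 m; translocated to 2 m for 48 h), with colonies
descending from seven mother colonies.  The deposited sequencing reads are
not desk-scale inputs, so this module generates statistically analogous
data with known truth:

* negative-binomial gene x sample count matrices under the 2x2
  entity x depth design with mother-colony batch effects and planted
  expression archetypes (frontloaded, higher-plasticity, both,
  responsive-only, null);
* gene -> GO annotations with planted enriched terms;
* per-sample MNP variant tables with an elevated multiallelic fraction in
  chimeras;
* HOBO-style temperature/light logger series per depth;
* Dirichlet-multinomial OTU tables; and binomial survival censuses.

All generators are deterministic given their seed; identical inputs
reproduce identical outputs byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .enrichment import GOAnnotation

__all__ = [
    "SimDesign",
    "SimParams",
    "LoggerProfile",
    "simulate_counts",
    "simulate_go_annotation",
    "simulate_variant_table",
    "simulate_logger",
    "simulate_otu_table",
    "simulate_survival_counts",
    "paper_like_design",
    "paper_like_params",
    "get_preset",
    "DEPTH_PROFILES",
]

ENTITIES = ("chimera", "nonchimera")
DEPTHS = ("10m", "2m")
_LN2 = np.log(2.0)

TRUTH_CATEGORIES = ("FRONTLOADED", "HIGHER_PLASTICITY",
                    "FRONTLOADED_AND_HIGHER_PLASTICITY",
                    "RESPONSIVE_ONLY", "NULL")


@dataclass
class SimDesign:
    """Sampling design: replicates per entity x depth cell and mothers."""

    n_genes: int = 2000
    replicates: dict = field(default_factory=lambda: {
        (e, d): 5 for e in ENTITIES for d in DEPTHS})
    mothers: tuple = ("A", "B", "C", "D", "E", "F", "G")
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        for cell in [(e, d) for e in ENTITIES for d in DEPTHS]:
            n = self.replicates.get(cell, 0)
            if n < 2:
                raise ValueError(f"design cell {cell} has {n} replicates; "
                                 "need at least 2")
        if not self.mothers:
            raise ValueError("at least one mother colony label required")


@dataclass
class SimParams:
    """Expression-model parameters.

    Log-fold-change parameters are in log2 units (converted to natural log
    internally); ``baseline_logmean_*`` and ``batch_sd`` are on the natural
    log scale of the NB mean.
    """

    baseline_logmean_mean: float = 5.0
    baseline_logmean_sd: float = 1.5
    dispersion: float = 0.1
    batch_sd: float = 0.5
    response_lfc: float = 2.0
    basal_shift_lfc: float = 2.0
    plasticity_gain_lfc: float = 1.0
    n_per_category: dict = field(default_factory=lambda: {
        "FRONTLOADED": 60, "HIGHER_PLASTICITY": 60,
        "FRONTLOADED_AND_HIGHER_PLASTICITY": 60, "RESPONSIVE_ONLY": 200})

    def validate(self, n_genes: int) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.batch_sd < 0:
            raise ValueError("batch_sd must be >= 0")
        for v in (self.response_lfc, self.basal_shift_lfc,
                  self.plasticity_gain_lfc):
            if not np.isfinite(v):
                raise ValueError("effect sizes must be finite")
        unknown = set(self.n_per_category) - set(TRUTH_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown planted categories: {sorted(unknown)}")
        if sum(self.n_per_category.values()) > n_genes:
            raise ValueError("planted categories exceed the gene universe")


def paper_like_design(seed: int = 0) -> SimDesign:
    """Five replicates per entity x depth cell, seven mothers, 2000 genes."""
    return SimDesign(seed=seed)


def paper_like_params() -> SimParams:
    return SimParams()


def get_preset(name: str, seed: int = 0) -> tuple[SimDesign, SimParams]:
    """Named study presets.

    ``paper-like``
        2000 genes, 5 samples per cell, 7 mothers, NB dispersion 0.1,
        response log2fc 2, basal shift 2, gain 1; planted 60/60/60
        frontloaded / higher-plasticity / both plus 200 responsive-only.
    ``frontload-dominant``
        Same sampling, but the chimera response is globally suppressed
        (300 frontloaded, 100 responsive-only, no amplified genes) — the
        regime in which chimeras show reduced transcriptomic plasticity.
    ``null``
        No planted effects at all (calibration runs).
    """
    design = paper_like_design(seed=seed)
    if name == "paper-like":
        return design, paper_like_params()
    if name == "frontload-dominant":
        return design, replace(paper_like_params(), n_per_category={
            "FRONTLOADED": 300, "RESPONSIVE_ONLY": 100})
    if name == "null":
        return design, replace(paper_like_params(), n_per_category={})
    raise ValueError(f"unknown preset {name!r}")


def _assign_categories(n_genes: int, n_per_category: dict,
                       rng: np.random.Generator) -> np.ndarray:
    cats = np.array(["NULL"] * n_genes, dtype=object)
    order = rng.permutation(n_genes)
    start = 0
    for cat in TRUTH_CATEGORIES[:-1]:
        n = int(n_per_category.get(cat, 0))
        cats[order[start:start + n]] = cat
        start += n
    return cats


def simulate_counts(design: SimDesign, params: SimParams
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate NB counts under the entity x depth design.

    Per gene g and sample j (entity e, depth d, mother m) the NB mean is
    ``exp(baseline_g + batch_{g,m} + effect_g(e, d))`` with common
    dispersion.  Effects, in natural-log units converted from the log2
    parameters:

    * every non-NULL gene responds by ``response_lfc`` (random sign per
      gene) in non-chimeras at 2 m;
    * FRONTLOADED genes add ``basal_shift_lfc`` in chimeras at both depths
      and do not respond in chimeras;
    * HIGHER_PLASTICITY genes respond by ``response_lfc * (1 + gain)`` in
      chimeras; FRONTLOADED_AND_HIGHER_PLASTICITY genes combine both;
    * RESPONSIVE_ONLY genes respond equally in both entities;
    * NULL genes carry no effects.

    Returns (counts genes x samples, sample metadata, truth labels).
    """
    design.validate()
    params.validate(design.n_genes)
    rng = np.random.default_rng(design.seed)
    g = design.n_genes

    baseline = rng.normal(params.baseline_logmean_mean,
                          params.baseline_logmean_sd, size=g)
    batch = rng.normal(0.0, params.batch_sd,
                       size=(g, len(design.mothers)))
    cats = _assign_categories(g, params.n_per_category, rng)
    sign = rng.choice([-1.0, 1.0], size=g)

    resp = params.response_lfc * _LN2 * sign
    basal = params.basal_shift_lfc * _LN2
    gain = params.plasticity_gain_lfc

    # per-gene effect components
    is_responsive = cats != "NULL"
    is_front = np.isin(cats, ["FRONTLOADED",
                              "FRONTLOADED_AND_HIGHER_PLASTICITY"])
    is_hp = np.isin(cats, ["HIGHER_PLASTICITY",
                           "FRONTLOADED_AND_HIGHER_PLASTICITY"])
    chim_resp = np.where(is_hp, resp * (1.0 + gain),
                         np.where(cats == "RESPONSIVE_ONLY", resp, 0.0))
    chim_basal = np.where(is_front, basal, 0.0)
    nonchim_resp = np.where(is_responsive, resp, 0.0)

    samples, meta_rows = [], []
    log_mu_cols = []
    cells = [(e, d) for e in ENTITIES for d in DEPTHS]
    for ci, (entity, depth) in enumerate(cells):
        for j in range(design.replicates[(entity, depth)]):
            # identical within-cell rotation keeps mothers balanced across
            # every pairwise contrast, so the covariate never aliases the
            # treatment column
            mother_idx = j % len(design.mothers)
            name = f"{'chim' if entity == 'chimera' else 'nonc'}_{depth}_r{j+1}"
            samples.append(name)
            meta_rows.append({"sample_id": name, "entity": entity,
                              "depth": depth,
                              "mother_colony": design.mothers[mother_idx]})
            eff = np.zeros(g)
            if entity == "chimera":
                eff += chim_basal
                if depth == "2m":
                    eff += chim_resp
            elif depth == "2m":
                eff += nonchim_resp
            log_mu_cols.append(baseline + batch[:, mother_idx] + eff)

    log_mu = np.column_stack(log_mu_cols)
    mu = np.exp(log_mu)
    if params.dispersion < 1e-8:
        counts = rng.poisson(mu)
    else:   # gamma-Poisson mixture == NB with the given dispersion
        lam = rng.gamma(shape=1.0 / params.dispersion,
                        scale=mu * params.dispersion)
        counts = rng.poisson(lam)
    gene_ids = [f"gene{i:05d}" for i in range(g)]
    counts_df = pd.DataFrame(counts.astype(np.int64), index=gene_ids,
                             columns=samples)
    counts_df.index.name = "gene_id"
    metadata = pd.DataFrame(meta_rows)
    truth = pd.Series(cats, index=gene_ids, name="category")
    return counts_df, metadata, truth


def simulate_go_annotation(n_genes: int, n_terms: int,
                           planted: dict | None = None, seed: int = 0,
                           with_parents: bool = False) -> GOAnnotation:
    """Random GO annotation over ``gene00000..`` with planted terms.

    Random term sizes are log-uniform in ``[5, 0.2 * n_genes]``; planted
    term -> gene-set entries are inserted verbatim.  With ``with_parents``
    each random term may link to an earlier term, which keeps the parent
    graph acyclic by construction.
    """
    planted = planted or {}
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    gene_set = set(genes)
    for term, members in planted.items():
        extra = set(members) - gene_set
        if extra:
            raise ValueError(f"planted term {term!r} has genes outside the "
                             f"universe: {sorted(extra)[:5]}")
    rng = np.random.default_rng(seed)
    gene_terms: dict[str, set] = {}
    parents: dict[str, set] = {}
    names: dict[str, str] = {}
    lo, hi = np.log(5.0), np.log(max(5.0, 0.2 * n_genes))
    term_ids = []
    for t in range(n_terms):
        term = f"GO:{t:07d}"
        term_ids.append(term)
        size = int(round(np.exp(rng.uniform(lo, hi))))
        size = min(max(size, 1), n_genes)
        members = rng.choice(n_genes, size=size, replace=False)
        for gi in members:
            gene_terms.setdefault(genes[gi], set()).add(term)
        names[term] = f"random process {t}"
        if with_parents and t > 0 and rng.random() < 0.3:
            parents[term] = {term_ids[rng.integers(0, t)]}
    for term, members in planted.items():
        for gid in members:
            gene_terms.setdefault(gid, set()).add(term)
        names.setdefault(term, term)
    return GOAnnotation(gene_terms=gene_terms, parents=parents,
                        term_names=names)


_BASES = np.array(list("ACGT"))


def _random_mnp_alleles(k: int, length: int, rng: np.random.Generator
                        ) -> list[str]:
    """k distinct sequences of the given length (first one is REF)."""
    alleles: list[str] = []
    while len(alleles) < k:
        seq = "".join(rng.choice(_BASES, size=length))
        if seq not in alleles:
            alleles.append(seq)
    return alleles


def simulate_variant_table(n_chimera: int = 11, n_nonchimera: int = 9,
                           n_loci: int = 200,
                           multiallelic_excess: float = 0.3,
                           base_multiallelic: float = 0.1,
                           seed: int = 0
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample MNP records with elevated multiallelic fraction in chimeras.

    Every sample carries ``n_loci`` MNP records (REF of 2-3 bases, ALTs of
    the same length).  A record is multiallelic (3 or 4 distinct alleles
    carried by the genotype) with probability ``base_multiallelic`` in
    non-chimeras and ``base_multiallelic + multiallelic_excess`` in
    chimeras, and biallelic otherwise.  Genotypes are written at ploidy 4
    (two expected diploid genomes per colony, the pooled-continuous
    calling convention).

    Returns (records, truth metadata).  Records have columns ``sample_id,
    chrom, pos, ref, alts, genotype``.
    """
    if n_loci <= 0:
        raise ValueError("n_loci must be positive")
    if multiallelic_excess < 0:
        raise ValueError("multiallelic_excess must be >= 0")
    p_chim = base_multiallelic + multiallelic_excess
    if not 0 <= p_chim <= 1:
        raise ValueError("base_multiallelic + multiallelic_excess must be "
                         "a probability")
    rng = np.random.default_rng(seed)
    rows, meta = [], []
    samples = ([(f"chim{i+1:02d}", "chimera", p_chim)
                for i in range(n_chimera)]
               + [(f"nonc{i+1:02d}", "nonchimera", base_multiallelic)
                  for i in range(n_nonchimera)])
    for sample_id, entity, p_multi in samples:
        meta.append({"sample_id": sample_id, "entity": entity})
        for locus in range(n_loci):
            multi = rng.random() < p_multi
            k = int(rng.integers(3, 5)) if multi else 2
            length = int(rng.integers(2, 4))
            alleles = _random_mnp_alleles(k, length, rng)
            gt = list(range(k)) + [k - 1] * (4 - k)   # ploidy 4, all alleles
            rows.append({"sample_id": sample_id, "chrom": "contig1",
                         "pos": 100 * (locus + 1), "ref": alleles[0],
                         "alts": ",".join(alleles[1:]),
                         "genotype": "/".join(map(str, gt))})
    return pd.DataFrame(rows), pd.DataFrame(meta)


@dataclass
class LoggerProfile:
    """Diel temperature/light profile of one depth."""

    temp_mean: float
    temp_amplitude: float
    light_peak: float
    noise_sd: float = 0.0


#: profiles emulating the two study platforms: the shallow platform is
#: warmer, more variable and far brighter than the deep one
DEPTH_PROFILES = {
    "2m": LoggerProfile(temp_mean=25.9, temp_amplitude=0.88,
                        light_peak=85000.0, noise_sd=0.05),
    "10m": LoggerProfile(temp_mean=25.37, temp_amplitude=0.53,
                         light_peak=12400.0, noise_sd=0.05),
}


def simulate_logger(profiles: dict[str, LoggerProfile] | None = None,
                    hours: int = 48, step_minutes: int = 10, seed: int = 0,
                    start: str = "2021-06-01T00:00:00") -> pd.DataFrame:
    """HOBO-style logger series: diel sinusoids plus Gaussian noise.

    Temperature follows ``mean + amplitude * sin(2 pi (h - 8) / 24)``
    (warmest mid-afternoon); light is a truncated sinusoid, zero outside
    06:00-18:00 and peaking at noon, scaled by ``light_peak``.  Records run
    from ``start`` inclusive at a fixed step, so 48 h at a 10-minute step
    yields 289 records per depth.
    """
    if hours <= 0:
        raise ValueError("hours must be positive")
    profiles = profiles or DEPTH_PROFILES
    rng = np.random.default_rng(seed)
    n = hours * 60 // step_minutes + 1
    t0 = pd.Timestamp(start)
    times = t0 + pd.to_timedelta(np.arange(n) * step_minutes, unit="m")
    hour = times.hour + times.minute / 60.0
    frames = []
    for depth, prof in profiles.items():
        temp = (prof.temp_mean
                + prof.temp_amplitude * np.sin(2 * np.pi * (hour - 8) / 24.0)
                + rng.normal(0.0, prof.noise_sd, size=n))
        light = prof.light_peak * np.clip(
            np.sin(np.pi * (hour - 6) / 12.0), 0.0, None)
        frames.append(pd.DataFrame({
            "timestamp": times.strftime("%Y-%m-%dT%H:%M:%S"),
            "temperature_C": np.round(temp, 3),
            "light_lux": np.round(light, 1),
            "depth": depth,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_otu_table(n_samples_per_group: dict | int = 5,
                       n_otus: int = 50,
                       base_proportions=None,
                       effect: float = 0.0,
                       library_size: int = 20000,
                       concentration: float = 200.0,
                       seed: int = 0
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dirichlet-multinomial OTU counts for the entity x depth groups.

    Per sample, proportions are drawn from a Dirichlet centered on
    ``base_proportions`` (total concentration controls overdispersion) and
    counts from a multinomial of ``library_size`` reads.  A non-zero
    ``effect`` perturbs the chimera groups' expected proportions by
    ``exp(+-effect)`` on alternating OTUs (renormalized), giving a
    known compositional group difference.
    """
    if library_size <= 0:
        raise ValueError("library size must be positive")
    if isinstance(n_samples_per_group, int):
        n_samples_per_group = {(e, d): n_samples_per_group
                               for e in ENTITIES for d in DEPTHS}
    rng = np.random.default_rng(seed)
    if base_proportions is None:
        w = rng.gamma(1.0, 1.0, size=n_otus)
        base_proportions = w / w.sum()
    base = np.asarray(base_proportions, dtype=float)
    if base.size != n_otus:
        raise ValueError("base_proportions length must equal n_otus")
    if not np.isclose(base.sum(), 1.0):
        raise ValueError("base_proportions must sum to 1")
    flip = np.where(np.arange(n_otus) % 2 == 0, 1.0, -1.0)
    otu_ids = [f"OTU{i+1:04d}" for i in range(n_otus)]
    cols, meta = {}, []
    for (entity, depth), n in sorted(n_samples_per_group.items()):
        props = base.copy()
        if effect != 0.0 and entity == "chimera":
            props = props * np.exp(effect * flip)
            props /= props.sum()
        for j in range(n):
            name = f"{'chim' if entity == 'chimera' else 'nonc'}_{depth}_m{j+1}"
            p = rng.dirichlet(props * concentration)
            cols[name] = rng.multinomial(library_size, p)
            meta.append({"sample_id": name, "entity": entity, "depth": depth})
    table = pd.DataFrame(cols, index=otu_ids)
    table.index.name = "otu_id"
    return table, pd.DataFrame(meta)


def simulate_survival_counts(n0_per_group: int = 80,
                             rate_chimera: float = 0.9,
                             rate_nonchimera: float = 0.75,
                             timepoints=(6, 12), seed: int = 0
                             ) -> pd.DataFrame:
    """Binomial survival censuses, monotone non-increasing within group.

    Rates are per-interval survival probabilities; survivors at each
    timepoint are drawn binomially from the previous census.
    """
    for r in (rate_chimera, rate_nonchimera):
        if not 0 <= r <= 1:
            raise ValueError("survival rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for group, rate in (("chimera", rate_chimera),
                        ("nonchimera", rate_nonchimera)):
        alive = n0_per_group
        for tp in timepoints:
            alive = int(rng.binomial(alive, rate))
            rows.append({"group": group, "timepoint": tp,
                         "n_alive": alive, "n_total": n0_per_group})
    return pd.DataFrame(rows)
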