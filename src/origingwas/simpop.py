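"""Synthetic admixed cattle-like populations with known ancestry and QTL.

The generator emulates the data structure an origin-aware association scan
assumes: two founder pools ("taurus" and "indicus") whose allele frequencies
diverged under drift, composite animals whose chromosomes are recent mosaics
of long founder tracts, QTL that segregate in one pool, in both (with the
same or reversed SNP linkage phase), or are fixed for alternate alleles,
and phenotypes with group offsets, a polygenic term and residual noise.

Divergence is modelled with the Balding–Nichols construction: for ancestral
frequency ``p`` and differentiation ``F`` each pool draws its frequency from
``Beta(p(1-F)/F, (1-p)(1-F)/F)``, which has mean ``p`` and variance
``F p(1-p)``.  Local linkage disequilibrium inside each founder pool is
induced by copying haplotypes from a small set of pool-specific template
haplotypes, so that multi-SNP segment haplotypes recur at estimable
frequencies.  Everything is driven by a single seed and is bit-reproducible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import BP_PER_MORGAN, HaplotypePanel, concat_panels, uniform_snp_map

QTL_MODES = (
    "taurus_only",
    "indicus_only",
    "shared_same_phase",
    "shared_reversed_phase",
    "fixed_difference",
)

GROUPS = ("taurus", "indicus", "composite")

TAURINE, INDICINE = 0, 1


@dataclass(frozen=True)
class QTLSpec:
    """One planted quantitative-trait locus.

    ``mode`` states where the causal mutation segregates; ``effect`` is the
    phenotypic effect per copy of the mutant allele in phenotypic SD units;
    ``mutant_freq`` is its frequency in each pool where it segregates; and
    ``mutant_allele`` is the SNP allele letter the mutation rides on (for
    ``shared_reversed_phase`` this is the phase in the taurus pool, reversed
    in the indicus pool).
    """

    chromosome: int
    snp_index: int
    mode: str
    effect: float
    mutant_freq: float = 0.5
    mutant_allele: str = "B"

    def __post_init__(self):
        if self.mode not in QTL_MODES:
            raise ValueError(f"unknown QTL mode {self.mode!r}")
        if self.mutant_allele not in ("A", "B"):
            raise ValueError("mutant_allele must be 'A' or 'B'")
        if self.mode != "fixed_difference" and not 0.0 < self.mutant_freq < 1.0:
            raise ValueError("mutant_freq must lie in (0, 1) for segregating modes")


@dataclass(frozen=True)
class SimulationConfig:
    n_chromosomes: int = 2
    snps_per_chromosome: int = 900
    # Dense-chip regime: a 30-SNP segment must be short in Morgans relative
    # to the ~1/admix_generations-Morgan ancestry tracts, as on a real HD
    # array.  900 SNPs on 0.25 Morgan puts ~15 segments inside a typical
    # 8-generation tract.
    chromosome_length: float = 0.25  # Morgans
    n_taurus: int = 250
    n_indicus: int = 250
    n_composite: int = 500
    divergence_fst: float = 0.3
    admix_generations: int = 8
    admix_proportion: float = 0.5
    qtl_specs: tuple[QTLSpec, ...] = ()
    heritability_polygenic: float = 0.3
    fixed_diff_fraction: float = 0.02
    n_templates: int = 20
    template_switch_rate: float = 0.02
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    group_offsets: tuple[float, float, float] = (0.0, 0.4, 0.2)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_chromosomes", "snps_per_chromosome", "n_taurus",
                     "n_indicus", "n_composite", "n_templates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.divergence_fst < 1.0:
            raise ValueError("divergence_fst must lie strictly in (0, 1)")
        if self.admix_generations < 1:
            raise ValueError("admix_generations must be >= 1")
        if not 0.0 < self.admix_proportion <= 1.0:
            raise ValueError("admix_proportion must lie in (0, 1]")
        if not 0.0 <= self.heritability_polygenic < 1.0:
            raise ValueError("heritability_polygenic must lie in [0, 1)")
        if not 0.0 <= self.fixed_diff_fraction < 1.0:
            raise ValueError("fixed_diff_fraction must lie in [0, 1)")
        if isinstance(self.qtl_specs, list):
            object.__setattr__(self, "qtl_specs", tuple(self.qtl_specs))
        for q in self.qtl_specs:
            if not 0 < q.chromosome <= self.n_chromosomes:
                raise ValueError(f"QTL chromosome {q.chromosome} outside the map")
            if not 0 <= q.snp_index < self.snps_per_chromosome:
                raise ValueError(f"QTL snp_index {q.snp_index} outside the map")


@dataclass
class TruthSet:
    """Ground truth retained for recovery tests.

    ``ancestry`` has one row per haplotype of the combined (taurus, indicus,
    composite) panel, 0 = taurine, 1 = indicine; ``tracts`` lists composite
    ancestry tracts in 0-based half-open bp coordinates; ``qtl`` records each
    planted locus with its global SNP column; ``polygenic`` holds the
    per-animal polygenic values actually added to the phenotype.
    """

    ancestry: np.ndarray
    tracts: pd.DataFrame
    qtl: pd.DataFrame = field(default_factory=pd.DataFrame)
    polygenic: np.ndarray | None = None


@dataclass
class SimulatedData:
    """Bundle returned by :func:`simulate_dataset`."""

    config: SimulationConfig
    panel: HaplotypePanel  # all animals, taurus | indicus | composite order
    groups: np.ndarray  # per-animal group label
    taurus: HaplotypePanel
    indicus: HaplotypePanel
    composite: HaplotypePanel
    phenotypes: pd.DataFrame
    truth: TruthSet

    def group_index(self, group: str) -> np.ndarray:
        return np.flatnonzero(self.groups == group)


def expected_ibd_tract_bp(generations: float, bp_per_morgan: float = BP_PER_MORGAN) -> float:
    """Expected length (bp) of an unbroken identity-by-descent segment.

    Recombination over ``g`` generations leaves IBD tracts of expected
    genetic length ``1/g`` Morgan; on a uniform map this converts to
    ``bp_per_morgan / g`` base pairs.  After 1e5 generations of divergence
    the expected shared segment is 1e-5 Morgan = 1 kb.
    """
    if generations <= 0:
        raise ValueError("generations must be positive")
    return bp_per_morgan / generations


def _qtl_global_index(config: SimulationConfig, q: QTLSpec) -> int:
    return (q.chromosome - 1) * config.snps_per_chromosome + q.snp_index


def _forced_qtl_frequencies(q: QTLSpec) -> tuple[float | None, float | None]:
    """B-allele frequency pair (taurus, indicus) implied by a QTLSpec.

    ``None`` leaves the drawn frequency untouched: for one-subspecies QTL
    the tag SNP may still segregate in the other pool — its alleles there
    belong to a different lineage and carry no effect (causal dosage is
    conditioned on true ancestry), so only the pool where the mutation
    segregates has its frequency pinned.
    """
    f = q.mutant_freq
    mutant_b = q.mutant_allele == "B"
    if q.mode == "fixed_difference":
        # causal lineage split: taurine alleles all A, indicine all B
        return 0.0, 1.0
    if q.mode == "taurus_only":
        return (f, None) if mutant_b else (1.0 - f, None)
    if q.mode == "indicus_only":
        return (None, f) if mutant_b else (None, 1.0 - f)
    if q.mode == "shared_same_phase":
        return (f, f) if mutant_b else (1.0 - f, 1.0 - f)
    # shared_reversed_phase: mutant on B in taurus, on A in indicus
    return (f, 1.0 - f) if mutant_b else (1.0 - f, f)


def simulate_founder_frequencies(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-SNP B-allele frequencies for the two founder pools.

    Balding–Nichols around a uniform ancestral frequency; a configured
    fraction of SNPs is forced to fixation for alternate alleles, and QTL
    sites are forced to the frequencies their segregation mode implies.
    """
    m = config.n_chromosomes * config.snps_per_chromosome
    fst = config.divergence_fst
    lo, hi = config.ancestral_freq_range
    anc = rng.uniform(lo, hi, size=m) if hi > lo else np.full(m, lo)
    shape = (1.0 - fst) / fst
    p_t = rng.beta(np.maximum(anc * shape, 1e-12), np.maximum((1 - anc) * shape, 1e-12))
    p_i = rng.beta(np.maximum(anc * shape, 1e-12), np.maximum((1 - anc) * shape, 1e-12))
    if config.fixed_diff_fraction > 0:
        n_fix = int(round(config.fixed_diff_fraction * m))
        sites = rng.choice(m, size=n_fix, replace=False)
        flip = rng.random(n_fix) < 0.5
        p_t[sites] = np.where(flip, 1.0, 0.0)
        p_i[sites] = np.where(flip, 0.0, 1.0)
    for q in config.qtl_specs:
        j = _qtl_global_index(config, q)
        ft, fi = _forced_qtl_frequencies(q)
        if ft is not None:
            p_t[j] = ft
        if fi is not None:
            p_i[j] = fi
    return p_t, p_i


def simulate_pure_haplotypes(
    freqs: np.ndarray,
    n_animals: int,
    rng: np.random.Generator,
    snp_map: pd.DataFrame,
    n_templates: int = 20,
    template_switch_rate: float = 0.02,
    group: str | None = None,
    id_prefix: str = "an",
) -> HaplotypePanel:
    """Sample a pure-pool panel with template-induced local LD.

    A pool of ``n_templates`` template haplotypes is drawn i.i.d. from the
    site frequencies; each sampled haplotype then copies from a template,
    switching to a random new template with probability
    ``template_switch_rate`` at each inter-SNP step (always at chromosome
    starts).  Large template counts recover the LD-free binomial limit.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    m = len(freqs)
    n_hap = 2 * n_animals
    templates = (rng.random((n_templates, m)) < freqs[None, :]).astype(np.int8)
    switch = rng.random((n_hap, m)) < template_switch_rate
    chrom = snp_map["chrom"].to_numpy()
    switch[:, 0] = True
    switch[:, np.flatnonzero(chrom[1:] != chrom[:-1]) + 1] = True
    seg_id = np.cumsum(switch, axis=1)  # >= 1
    choice = rng.integers(0, n_templates, size=(n_hap, int(seg_id.max()) + 1))
    tmpl_idx = np.take_along_axis(choice, seg_id, axis=1)
    haps = templates[tmpl_idx, np.arange(m)[None, :]]
    # Monomorphic sites stay exactly monomorphic regardless of templates.
    haps[:, freqs == 0.0] = 0
    haps[:, freqs == 1.0] = 1
    ids = np.array([f"{id_prefix}{k:05d}" for k in range(n_animals)], dtype=object)
    return HaplotypePanel(snp_map=snp_map, haplotypes=haps, animal_ids=ids, group=group)


def simulate_composite_haplotypes(
    taurus_pool: HaplotypePanel,
    indicus_pool: HaplotypePanel,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[HaplotypePanel, np.ndarray, pd.DataFrame]:
    """Build composite haplotypes as tract mosaics of the two pools.

    Tract genetic lengths are exponential with mean ``1/admix_generations``
    Morgans (the renewal approximation to recombination since admixture);
    each tract's source pool is drawn independently with the configured
    indicine proportion, and its alleles are copied from one uniformly
    chosen haplotype of that pool.  Returns the panel, per-haplotype
    per-SNP true ancestry labels, and the tract table (0-based half-open bp).
    """
    if taurus_pool.haplotypes.shape[0] == 0 or indicus_pool.haplotypes.shape[0] == 0:
        raise ValueError("both source pools must be non-empty")
    snp_map = taurus_pool.snp_map
    gen_pos = snp_map["gen_pos"].to_numpy()
    chrom = snp_map["chrom"].to_numpy()
    n_hap = 2 * config.n_composite
    m = len(snp_map)
    haps = np.empty((n_hap, m), dtype=np.int8)
    ancestry = np.empty((n_hap, m), dtype=np.int8)
    pools = (taurus_pool.haplotypes, indicus_pool.haplotypes)
    mean_len = 1.0 / config.admix_generations
    tract_rows = []
    blocks = taurus_pool.chromosome_blocks()
    for h in range(n_hap):
        for c, sl in blocks:
            g = gen_pos[sl]
            lo, hi = g[0], g[-1]
            start = 0.0
            # oversample breakpoints, then walk tracts
            while True:
                n_draw = max(8, int(3 * config.admix_generations * config.chromosome_length))
                lengths = rng.exponential(mean_len, size=n_draw)
                ends = np.cumsum(lengths)
                if ends[-1] > config.chromosome_length:
                    break
            cuts = np.concatenate([[0.0], ends[ends < config.chromosome_length],
                                   [config.chromosome_length]])
            for t in range(len(cuts) - 1):
                origin = INDICINE if rng.random() < config.admix_proportion else TAURINE
                in_tract = (g >= cuts[t]) & (g < cuts[t + 1])
                idx = np.flatnonzero(in_tract)
                start_bp = int(round(cuts[t] * BP_PER_MORGAN))
                end_bp = int(round(cuts[t + 1] * BP_PER_MORGAN))
                tract_rows.append((c, h, start_bp, end_bp, "indicine" if origin else "taurine"))
                if idx.size == 0:
                    continue
                src = pools[origin]
                donor = rng.integers(0, src.shape[0])
                cols = np.arange(sl.start, sl.stop)[idx]
                haps[h, cols] = src[donor, cols]
                ancestry[h, cols] = origin
    ids = np.array([f"cp{k:05d}" for k in range(config.n_composite)], dtype=object)
    panel = HaplotypePanel(snp_map=snp_map, haplotypes=haps, animal_ids=ids, group="composite")
    tracts = pd.DataFrame(tract_rows, columns=["chrom", "hap_id", "start_bp", "end_bp", "origin"])
    return panel, ancestry, tracts


def causal_dosage(
    alleles: np.ndarray, ancestry: np.ndarray, spec: QTLSpec, snp_col: int
) -> np.ndarray:
    """Per-animal count (0/1/2) of causal-lineage alleles at a QTL column.

    The mutation is identified by allele letter *and* true ancestry: a B
    allele of indicine origin at a taurus-only QTL is a different lineage
    and carries no effect.  This is what creates origin-by-allele
    interaction signal in the phenotype.
    """
    a = alleles[:, snp_col]
    o = ancestry[:, snp_col]
    mut = 1 if spec.mutant_allele == "B" else 0
    if spec.mode == "taurus_only":
        hit = (a == mut) & (o == TAURINE)
    elif spec.mode == "indicus_only":
        hit = (a == mut) & (o == INDICINE)
    elif spec.mode == "shared_same_phase":
        hit = a == mut
    elif spec.mode == "shared_reversed_phase":
        hit = ((a == mut) & (o == TAURINE)) | ((a == 1 - mut) & (o == INDICINE))
    elif spec.mode == "fixed_difference":
        hit = o == INDICINE
    else:  # pragma: no cover
        raise ValueError(spec.mode)
    hit = hit.astype(float)
    return hit[0::2] + hit[1::2]


def simulate_phenotypes(
    panel: HaplotypePanel,
    ancestry: np.ndarray,
    groups: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    grm_chol: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Phenotypes = group offset + QTL effects + polygenic value + noise.

    The phenotypic variance is anchored at 1: QTL variance (empirical, at
    the realised dosages) plus the configured polygenic fraction must stay
    below 1 and the residual takes the remainder.  Returns the phenotype
    table, the QTL truth table, and the polygenic values.
    """
    n = panel.n_animals
    y = np.zeros(n)
    offsets = dict(zip(GROUPS, config.group_offsets))
    for g, off in offsets.items():
        y[groups == g] += off
    qtl_rows = []
    qtl_var = 0.0
    for q in config.qtl_specs:
        j = _qtl_global_index(config, q)
        d = causal_dosage(panel.haplotypes, ancestry, q, j)
        y += q.effect * d
        v = float(np.var(d)) * q.effect**2
        qtl_var += v
        qtl_rows.append(
            (q.chromosome, q.snp_index, j, q.mode, q.effect, q.mutant_freq,
             q.mutant_allele, v)
        )
    h2 = config.heritability_polygenic
    if h2 + qtl_var >= 1.0:
        raise ValueError(
            f"polygenic ({h2:.3f}) + QTL ({qtl_var:.3f}) variance reaches 1; "
            "lower effects or heritability"
        )
    if h2 > 0:
        if grm_chol is None:
            from .assoc import vanraden_grm

            g_mat = vanraden_grm(panel.dosage())
            grm_chol = np.linalg.cholesky(g_mat + 1e-6 * np.eye(n))
        poly = grm_chol @ rng.standard_normal(n)
        # normalise to the configured variance given the realised GRM scale
        sd = float(np.std(poly))
        if sd > 0:
            poly *= math.sqrt(h2) / sd
    else:
        poly = np.zeros(n)
    y += poly
    sigma_e = math.sqrt(1.0 - h2 - qtl_var)
    y += rng.normal(0.0, sigma_e, size=n)
    phen = pd.DataFrame(
        {"animal_id": panel.animal_ids, "group": groups, "y": y}
    )
    qtl = pd.DataFrame(
        qtl_rows,
        columns=["chromosome", "snp_index", "snp_col", "mode", "effect",
                 "mutant_freq", "mutant_allele", "realised_var"],
    )
    return phen, qtl, poly


def simulate_dataset(config: SimulationConfig) -> SimulatedData:
    """Run the full generator: founders, pools, composites, phenotypes, truth."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    snp_map = uniform_snp_map(
        config.n_chromosomes, config.snps_per_chromosome, config.chromosome_length
    )
    p_t, p_i = simulate_founder_frequencies(config, rng)
    taurus = simulate_pure_haplotypes(
        p_t, config.n_taurus, rng, snp_map, config.n_templates,
        config.template_switch_rate, group="taurus", id_prefix="bt",
    )
    indicus = simulate_pure_haplotypes(
        p_i, config.n_indicus, rng, snp_map, config.n_templates,
        config.template_switch_rate, group="indicus", id_prefix="bi",
    )
    composite, comp_anc, tracts = simulate_composite_haplotypes(
        taurus, indicus, config, rng
    )
    panel = concat_panels([taurus, indicus, composite])
    groups = np.concatenate([
        np.repeat("taurus", config.n_taurus),
        np.repeat("indicus", config.n_indicus),
        np.repeat("composite", config.n_composite),
    ])
    ancestry = np.vstack([
        np.zeros_like(taurus.haplotypes, dtype=np.int8),
        np.ones_like(indicus.haplotypes, dtype=np.int8),
        comp_anc,
    ])
    phen, qtl, poly = simulate_phenotypes(panel, ancestry, groups, config, rng)
    truth = TruthSet(ancestry=ancestry, tracts=tracts, qtl=qtl, polygenic=poly)
    return SimulatedData(
        config=config, panel=panel, groups=groups, taurus=taurus,
        indicus=indicus, composite=composite, phenotypes=phen, truth=truth,
    )
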