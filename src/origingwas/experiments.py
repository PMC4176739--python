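"""Canned simulation studies: power, calibration and recovery experiments.

Each function simulates data with :mod:`origingwas.simpop`, runs the
relevant pipeline stage, and returns summary numbers.  They are used both
by the test suite and by the repository's results-reproduction script, so
the experimental conditions (sample sizes, effect sizes, replicate counts)
are fixed here in one place.

The association experiments feed the scans the *true* ancestry labels so
that they measure properties of the models themselves; ancestry-inference
quality is measured separately by :func:`ancestry_accuracy_experiment`.
"""
from __future__ import annotations

import numpy as np

from .ancestry import AlleleOriginMatrix, ancestry_fraction_report, infer_ancestry
from .assoc import (
    GwasDataset,
    fit_null_model,
    gls_scan,
    run_best_variable_gwas,
    run_interaction_gwas,
    vanraden_grm,
)
from .report import estimate_fdr
from .simpop import (
    QTLSpec,
    SimulatedData,
    SimulationConfig,
    simulate_dataset,
    simulate_phenotypes,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Independent 31-bit child seeds derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def true_origin_matrix(sim: SimulatedData) -> AlleleOriginMatrix:
    """Allele-origin matrix using the simulated truth instead of inference."""
    return AlleleOriginMatrix(
        alleles=sim.panel.haplotypes,
        origins=sim.truth.ancestry,
        animal_ids=sim.panel.animal_ids,
        snp_map=sim.panel.snp_map,
    )


def ancestry_accuracy_experiment(
    seed: int,
    fst: float = 0.3,
    n_ref: int = 250,
    n_composite: int = 200,
    admix_generations: int = 8,
    admix_proportion: float = 0.5,
    n_chromosomes: int = 3,
    snps_per_chromosome: int = 900,
) -> dict:
    """Classify simulated composites against the known tract ancestry.

    Returns the fraction of composite alleles whose inferred origin matches
    the truth and the group-level indicine segment fraction alongside the
    configured admixture proportion.
    """
    cfg = SimulationConfig(
        n_chromosomes=n_chromosomes,
        snps_per_chromosome=snps_per_chromosome,
        n_taurus=n_ref,
        n_indicus=n_ref,
        n_composite=n_composite,
        divergence_fst=fst,
        admix_generations=admix_generations,
        admix_proportion=admix_proportion,
        heritability_polygenic=0.0,
        seed=seed,
    )
    sim = simulate_dataset(cfg)
    origins, aom = infer_ancestry(sim.composite, sim.taurus, sim.indicus)
    truth = sim.truth.ancestry[2 * (n_ref + n_ref):]
    accuracy = float((aom.origins == truth).mean())
    _, per_group, _ = ancestry_fraction_report(
        origins, np.repeat("composite", n_composite)
    )
    fraction = float(per_group["mean"].iloc[0])
    return {
        "allele_accuracy": accuracy,
        "group_indicine_fraction": fraction,
        "admix_proportion": admix_proportion,
        "true_fraction": float(truth.mean()),
        "n_alleles": int(truth.size),
    }


def _spread_qtl(
    n_chromosomes: int, snps_per_chromosome: int, n_qtl: int, mode: str,
    effect: float, rng: np.random.Generator, mutant_allele: str = "B",
) -> tuple[QTLSpec, ...]:
    """Evenly spaced QTL over the genome with frequencies drawn near 0.5."""
    per_chrom = n_qtl // n_chromosomes
    specs = []
    for c in range(1, n_chromosomes + 1):
        step = snps_per_chromosome // (per_chrom + 1)
        for k in range(per_chrom):
            freq = float(rng.uniform(0.3, 0.7))
            specs.append(QTLSpec(c, step * (k + 1), mode, effect, freq, mutant_allele))
    return tuple(specs)


def power_experiment(
    seed: int,
    n_replicates: int = 10,
    n_qtl_per_replicate: int = 10,
    effect: float = 0.3,
    n_composite: int = 3000,
    mode: str = "shared_reversed_phase",
    heritability: float = 0.3,
    threshold: float = 1e-4,
    n_chromosomes: int = 2,
    snps_per_chromosome: int = 500,
) -> dict:
    """Conventional versus interaction GWAS power at causal tag SNPs.

    Each replicate plants evenly spaced QTL (phase reversed between the
    subspecies by default), phenotypes composite animals with a polygenic
    background, and counts causal SNPs declared significant by the
    conventional x1 test and by the 3-df interaction joint test.
    """
    conv_hits = 0
    inter_hits = 0
    n_true = 0
    for rep_seed in _child_seeds(seed, n_replicates):
        rng = np.random.default_rng(rep_seed)
        qtl = _spread_qtl(n_chromosomes, snps_per_chromosome, n_qtl_per_replicate,
                          mode, effect, rng)
        cfg = SimulationConfig(
            n_chromosomes=n_chromosomes,
            snps_per_chromosome=snps_per_chromosome,
            n_taurus=100,
            n_indicus=100,
            n_composite=n_composite,
            qtl_specs=qtl,
            heritability_polygenic=heritability,
            seed=rep_seed,
        )
        sim = simulate_dataset(cfg)
        aom = true_origin_matrix(sim)
        idx = sim.group_index("composite")
        sub_aom = AlleleOriginMatrix(
            alleles=aom.alleles[np.repeat(2 * idx, 2) + np.tile([0, 1], idx.size)],
            origins=aom.origins[np.repeat(2 * idx, 2) + np.tile([0, 1], idx.size)],
            animal_ids=aom.animal_ids[idx],
            snp_map=aom.snp_map,
        )
        grm = None
        if heritability > 0:
            grm = vanraden_grm(sim.panel.dosage()[idx])
        ds = GwasDataset(
            aom=sub_aom,
            phenotypes=sim.phenotypes.iloc[idx].reset_index(drop=True),
            groups=sim.groups[idx],
            grm=grm,
        )
        qtl_cols = sim.truth.qtl["snp_col"].to_numpy()
        null = fit_null_model(
            ds.phenotypes["y"].to_numpy(), ds.covariates(np.arange(idx.size)), grm
        )
        # scan only the causal tag columns: power is scored at the QTL
        from .design import variable_matrix

        conv = gls_scan(null, {"x1": variable_matrix(sub_aom, "x1")[:, qtl_cols]})
        inter = gls_scan(
            null,
            {v: variable_matrix(sub_aom, v)[:, qtl_cols] for v in ("x1", "x2", "x3")},
        )
        conv_hits += int((conv.p_marginal[:, 0] < threshold).sum())
        inter_hits += int((inter.joint_p < threshold).sum())
        n_true += len(qtl_cols)
    return {
        "conventional_hits": conv_hits,
        "interaction_hits": inter_hits,
        "n_true_snps": n_true,
        "threshold": threshold,
    }


def pattern_recovery_experiment(
    seed: int,
    mode: str = "taurus_only",
    mutant_allele: str = "A",
    n_replicates: int = 50,
    effect: float = 0.5,
    n_composite: int = 2000,
    n_pure: int = 500,
    snps_per_chromosome: int = 300,
) -> dict:
    """How often the best-variable scan names the right contrast at the QTL.

    Plants one within-subspecies QTL per replicate and checks which single
    variable wins at the causal SNP.  For a taurus-only QTL the expected
    winners are x4/x6 (x4 when the mutant rides allele A); symmetrically
    x5/x7 for indicus-only.  Replicates omit the polygenic term: with a
    0.5-SD causal effect it only rescales all six single-variable tests.
    """
    expected = {"taurus_only": ("x4", "x6"), "indicus_only": ("x5", "x7")}[mode]
    strict = {"taurus_only": {"A": "x4", "B": "x6"},
              "indicus_only": {"A": "x5", "B": "x7"}}[mode][mutant_allele]
    hits = 0
    strict_hits = 0
    qtl_index = snps_per_chromosome // 2
    for rep_seed in _child_seeds(seed, n_replicates):
        rng = np.random.default_rng(rep_seed)
        freq = float(rng.uniform(0.3, 0.7))
        cfg = SimulationConfig(
            n_chromosomes=1,
            snps_per_chromosome=snps_per_chromosome,
            n_taurus=n_pure,
            n_indicus=n_pure,
            n_composite=n_composite,
            qtl_specs=(QTLSpec(1, qtl_index, mode, effect, freq, mutant_allele),),
            heritability_polygenic=0.0,
            seed=rep_seed,
        )
        sim = simulate_dataset(cfg)
        ds = GwasDataset(
            aom=true_origin_matrix(sim),
            phenotypes=sim.phenotypes,
            groups=sim.groups,
            grm=None,
        )
        best = run_best_variable_gwas(ds)
        winner = best["best_variable"].iloc[qtl_index]
        hits += winner in expected
        strict_hits += winner == strict
    return {
        "mode": mode,
        "mutant_allele": mutant_allele,
        "fraction_expected_pair": hits / n_replicates,
        "fraction_expected_strict": strict_hits / n_replicates,
        "n_replicates": n_replicates,
    }


def null_calibration_experiment(
    seed: int,
    n_animals: int = 2000,
    n_snps: int = 5000,
    heritability: float = 0.3,
    threshold: float = 1e-4,
) -> dict:
    """Type-I behaviour of the interaction joint test under the global null.

    No QTL are planted; the phenotype is polygenic background plus noise.
    Returns the fraction of testable SNPs with joint p below the threshold
    and the expected-by-chance FDR summary of that scan.
    """
    n_comp = n_animals // 2
    n_pure = (n_animals - n_comp) // 2
    cfg = SimulationConfig(
        n_chromosomes=5,
        snps_per_chromosome=n_snps // 5,
        n_taurus=n_pure,
        n_indicus=n_pure,
        n_composite=n_comp,
        heritability_polygenic=heritability,
        seed=seed,
    )
    sim = simulate_dataset(cfg)
    grm = vanraden_grm(sim.panel.dosage())
    ds = GwasDataset(
        aom=true_origin_matrix(sim),
        phenotypes=sim.phenotypes,
        groups=sim.groups,
        grm=grm,
    )
    inter = run_interaction_gwas(ds)
    p = inter["joint_p"].to_numpy()
    tested = int(np.isfinite(p).sum())
    sig = int((p[np.isfinite(p)] < threshold).sum())
    fdr = estimate_fdr(sig, tested, threshold)
    return {
        "n_tested": tested,
        "n_significant": sig,
        "fraction_significant": sig / tested,
        "threshold": threshold,
        "fdr_percent": fdr.fdr_percent,
        "fdr_is_na": fdr.is_na(),
    }


def model_equivalence_experiment(
    seed: int, n_animals: int = 1000, n_snps: int = 200
) -> dict:
    """Maximum relative gap between the two interaction parameterisations.

    Both {x1, x2, x3} and {x2, x6, x7} span the same SNP-term column space,
    so their joint Wald statistics must agree wherever both are full rank.
    """
    cfg = SimulationConfig(
        n_chromosomes=1,
        snps_per_chromosome=n_snps,
        n_taurus=150,
        n_indicus=150,
        n_composite=n_animals - 300,
        heritability_polygenic=0.3,
        seed=seed,
    )
    sim = simulate_dataset(cfg)
    grm = vanraden_grm(sim.panel.dosage())
    ds = GwasDataset(
        aom=true_origin_matrix(sim), phenotypes=sim.phenotypes,
        groups=sim.groups, grm=grm,
    )
    inter = run_interaction_gwas(ds)
    both = (inter["joint_df"] == 3) & (inter["joint_df_reparam"] == 3)
    s1 = inter.loc[both, "joint_stat"].to_numpy()
    s2 = inter.loc[both, "joint_stat_reparam"].to_numpy()
    rel = np.abs(s1 - s2) / np.maximum(np.abs(s1), 1e-300)
    return {
        "max_rel_diff": float(rel.max()),
        "n_compared": int(both.sum()),
        "n_snps": n_snps,
    }


def h2_recovery_experiment(
    seed: int,
    heritability: float = 0.4,
    n_animals: int = 2000,
    n_replicates: int = 20,
) -> dict:
    """REML recovery of the simulated polygenic heritability.

    One genotype panel is simulated; phenotypes are redrawn per replicate
    (polygenic plus residual, no QTL) and the null model refitted.  The GRM
    eigendecomposition is shared across replicates.
    """
    n_comp = n_animals // 2
    n_pure = (n_animals - n_comp) // 2
    cfg = SimulationConfig(
        n_chromosomes=2,
        snps_per_chromosome=500,
        n_taurus=n_pure,
        n_indicus=n_pure,
        n_composite=n_comp,
        heritability_polygenic=heritability,
        seed=seed,
    )
    sim = simulate_dataset(cfg)
    grm = vanraden_grm(sim.panel.dosage())
    chol = np.linalg.cholesky(grm + 1e-6 * np.eye(n_animals))
    s, U = np.linalg.eigh(grm)
    X = np.column_stack([
        np.ones(n_animals),
        (sim.groups == "indicus").astype(float),
        (sim.groups == "composite").astype(float),
    ])
    estimates = []
    for rep_seed in _child_seeds(seed + 1, n_replicates):
        rng = np.random.default_rng(rep_seed)
        phen, _, _ = simulate_phenotypes(
            sim.panel, sim.truth.ancestry, sim.groups, cfg, rng, grm_chol=chol
        )
        fit = fit_null_model(phen["y"].to_numpy(), X, (s, U))
        estimates.append(fit.h2)
    return {
        "h2_true": heritability,
        "h2_mean": float(np.mean(estimates)),
        "h2_sd": float(np.std(estimates)),
        "n_replicates": n_replicates,
    }
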