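"""Generator checks: divergence, LD, tracts, phenotype model, determinism."""
import numpy as np
import pytest

import origingwas as og
from origingwas.simpop import causal_dosage, simulate_phenotypes


def hudson_fst(p1, p2):
    """Frequency-based Hudson estimator (ratio of averages)."""
    num = np.mean((p1 - p2) ** 2)
    den = np.mean(p1 * (1 - p2) + p2 * (1 - p1))
    return num / den


class TestFounderFrequencies:
    def test_fst_recovered_by_hudson_estimator(self):
        cfg = og.SimulationConfig(
            n_chromosomes=1, snps_per_chromosome=10_000, divergence_fst=0.5,
            ancestral_freq_range=(0.5, 0.5), fixed_diff_fraction=0.0, seed=5,
        )
        rng = np.random.default_rng(5)
        p_t, p_i = og.simulate_founder_frequencies(cfg, rng)
        assert hudson_fst(p_t, p_i) == pytest.approx(0.5, abs=0.02)

    def test_low_fst_limit_shrinks_divergence(self):
        rng = np.random.default_rng(0)
        cfg = og.SimulationConfig(
            n_chromosomes=1, snps_per_chromosome=5000, divergence_fst=0.01,
            fixed_diff_fraction=0.0, seed=0,
        )
        p_t, p_i = og.simulate_founder_frequencies(cfg, rng)
        assert np.mean(np.abs(p_t - p_i)) < 0.06

    @pytest.mark.parametrize("fst", [0.0, 1.0])
    def test_degenerate_fst_rejected(self, fst):
        with pytest.raises(ValueError):
            og.SimulationConfig(divergence_fst=fst)

    def test_fixed_difference_qtl_site_is_alternately_fixed(self):
        q = og.QTLSpec(1, 10, "fixed_difference", 0.3)
        cfg = og.SimulationConfig(
            n_chromosomes=1, snps_per_chromosome=100, qtl_specs=(q,), seed=2
        )
        p_t, p_i = og.simulate_founder_frequencies(cfg, np.random.default_rng(2))
        assert p_t[10] == 0.0 and p_i[10] == 1.0

    def test_qtl_outside_map_rejected(self):
        with pytest.raises(ValueError):
            og.SimulationConfig(
                n_chromosomes=1, snps_per_chromosome=100,
                qtl_specs=(og.QTLSpec(1, 100, "taurus_only", 0.5),),
            )


class TestPureHaplotypes:
    def test_monomorphic_site_stays_monomorphic(self):
        snp_map = og.uniform_snp_map(1, 10, 0.25)
        freqs = np.zeros(10)
        panel = og.simulate_pure_haplotypes(freqs, 20, np.random.default_rng(1), snp_map)
        assert (panel.haplotypes == 0).all()

    def test_sample_frequency_converges_in_large_template_limit(self):
        snp_map = og.uniform_snp_map(1, 40, 0.25)
        freqs = np.full(40, 0.3)
        panel = og.simulate_pure_haplotypes(
            freqs, 2000, np.random.default_rng(7), snp_map, n_templates=4000
        )
        se = np.sqrt(0.3 * 0.7 * (1 / 4000 + 1 / 4000))
        obs = panel.allele_frequency()
        assert np.all(np.abs(obs - 0.3) < 4 * se)

    def test_segment_haplotypes_recur_with_default_templates(self):
        # local LD: 30-SNP strings must be shared across the pool
        snp_map = og.uniform_snp_map(1, 30, 0.01)
        freqs = np.random.default_rng(3).uniform(0.2, 0.8, 30)
        panel = og.simulate_pure_haplotypes(freqs, 100, np.random.default_rng(3), snp_map)
        strings = {row.tobytes() for row in panel.haplotypes}
        # i.i.d. sites would make essentially all 200 strings unique
        assert len(strings) < 150

    def test_same_seed_reproduces_panel(self):
        cfg = og.SimulationConfig(n_chromosomes=1, snps_per_chromosome=50,
                                  n_taurus=10, n_indicus=10, n_composite=10, seed=42)
        a = og.simulate_dataset(cfg)
        b = og.simulate_dataset(cfg)
        assert np.array_equal(a.panel.haplotypes, b.panel.haplotypes)
        assert np.array_equal(a.truth.ancestry, b.truth.ancestry)
        assert a.phenotypes["y"].equals(b.phenotypes["y"])


@pytest.fixture(scope="module")
def long_chrom_sim():
    cfg = og.SimulationConfig(
        n_chromosomes=1, snps_per_chromosome=600, chromosome_length=1.0,
        n_taurus=50, n_indicus=50, n_composite=500, admix_generations=8,
        heritability_polygenic=0.0, seed=13,
    )
    return og.simulate_dataset(cfg)


class TestComposites:
    def test_first_tract_length_matches_censored_exponential_mean(self, long_chrom_sim):
        # completed tracts inside a fixed window are length-biased, so test
        # the first tract per haplotype: length min(Exp(1/G), L) with mean
        # (1 - exp(-G L)) / G, ~= 1/G = 0.125 Morgan at G=8, L=1
        tr = long_chrom_sim.truth.tracts
        first = tr.groupby(["hap_id", "chrom"], as_index=False).first()
        lengths = (first["end_bp"] - first["start_bp"]).to_numpy() / 1e8
        expected = (1 - np.exp(-8.0)) / 8.0
        se = lengths.std() / np.sqrt(len(lengths))
        assert lengths.mean() == pytest.approx(expected, abs=3.5 * se)

    def test_tract_count_matches_poisson_breakpoints(self, long_chrom_sim):
        # E[#tracts per 1-Morgan chromosome] = 1 + G*L = 9
        counts = long_chrom_sim.truth.tracts.groupby(["hap_id", "chrom"]).size()
        assert counts.mean() == pytest.approx(9.0, rel=0.05)

    def test_genomewide_indicine_fraction_matches_admix_proportion(self, long_chrom_sim):
        frac = long_chrom_sim.truth.ancestry[2 * 100:].mean()
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_full_indicine_proportion_gives_constant_labels(self):
        cfg = og.SimulationConfig(
            n_chromosomes=1, snps_per_chromosome=100, n_taurus=20, n_indicus=20,
            n_composite=30, admix_proportion=1.0, heritability_polygenic=0.0, seed=4,
        )
        sim = og.simulate_dataset(cfg)
        assert (sim.truth.ancestry[2 * 40:] == 1).all()

    def test_alleles_copied_from_tract_origin_pool(self, long_chrom_sim):
        # ancestry conservation: at sites fixed for alternate alleles the
        # composite allele letter must equal its tract's origin
        sim = long_chrom_sim
        p_t = sim.taurus.allele_frequency()
        p_i = sim.indicus.allele_frequency()
        fixed = (p_t == 0) & (p_i == 1)
        assert fixed.sum() > 0
        comp = sim.composite.haplotypes[:, fixed]
        anc = sim.truth.ancestry[2 * 100:][:, fixed]
        assert np.array_equal(comp, anc)


class TestPhenotypes:
    def test_pure_noise_when_no_effects(self):
        cfg = og.SimulationConfig(
            n_chromosomes=1, snps_per_chromosome=200, n_taurus=50, n_indicus=50,
            n_composite=2000, heritability_polygenic=0.0, group_offsets=(0, 0, 0),
            seed=8,
        )
        sim = og.simulate_dataset(cfg)
        assert sim.phenotypes["y"].var() == pytest.approx(1.0, abs=0.08)

    def test_ols_recovers_single_qtl_effect(self):
        q = og.QTLSpec(1, 100, "shared_same_phase", 0.5, 0.5)
        cfg = og.SimulationConfig(
            n_chromosomes=1, snps_per_chromosome=200, n_taurus=50, n_indicus=50,
            n_composite=2000, qtl_specs=(q,), heritability_polygenic=0.0, seed=9,
        )
        sim = og.simulate_dataset(cfg)
        idx = sim.group_index("composite")
        d = causal_dosage(sim.panel.haplotypes, sim.truth.ancestry, q, 100)[idx]
        y = sim.phenotypes["y"].to_numpy()[idx]
        X = np.column_stack([np.ones(idx.size), d])
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma2 = res[0] / (idx.size - 2)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert beta[1] == pytest.approx(0.5, abs=3 * se)

    def test_taurus_only_qtl_silent_in_indicus_group(self):
        q = og.QTLSpec(1, 100, "taurus_only", 0.5, 0.5)
        cfg = og.SimulationConfig(
            n_chromosomes=1, snps_per_chromosome=200, n_taurus=400, n_indicus=2000,
            n_composite=50, qtl_specs=(q,), heritability_polygenic=0.0, seed=11,
        )
        sim = og.simulate_dataset(cfg)
        idx = sim.group_index("indicus")
        d = sim.panel.dosage()[idx, 100]
        y = sim.phenotypes["y"].to_numpy()[idx]
        assert np.std(d) > 0  # tag SNP segregates in indicus under this seed
        X = np.column_stack([np.ones(idx.size), d])
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        se = np.sqrt(res[0] / (idx.size - 2) * np.linalg.inv(X.T @ X)[1, 1])
        assert abs(beta[1]) < 3 * se

    def test_variance_accounting_over_replicates(self):
        cfg = og.SimulationConfig(
            n_chromosomes=1, snps_per_chromosome=400, n_taurus=100, n_indicus=100,
            n_composite=1800, heritability_polygenic=0.4, seed=21,
        )
        sim = og.simulate_dataset(cfg)
        grm = og.vanraden_grm(sim.panel.dosage())
        chol = np.linalg.cholesky(grm + 1e-6 * np.eye(sim.panel.n_animals))
        h2s = []
        for k in range(50):
            rng = np.random.default_rng(1000 + k)
            _, _, poly = simulate_phenotypes(
                sim.panel, sim.truth.ancestry, sim.groups, cfg, rng, grm_chol=chol
            )
            h2s.append(np.var(poly))
        assert np.mean(h2s) == pytest.approx(0.4, abs=0.05)

    def test_excess_variance_rejected(self):
        q = og.QTLSpec(1, 10, "shared_same_phase", 2.0, 0.5)
        cfg = og.SimulationConfig(
            n_chromosomes=1, snps_per_chromosome=50, n_taurus=30, n_indicus=30,
            n_composite=100, qtl_specs=(q,), heritability_polygenic=0.5, seed=3,
        )
        with pytest.raises(ValueError, match="variance"):
            og.simulate_dataset(cfg)


def test_ibd_tract_arithmetic():
    # divergence over 1e5 generations -> 1e-5 Morgan -> 1 kb on a 1 cM/Mb map
    assert og.expected_ibd_tract_bp(1e5) == pytest.approx(1000.0)
    assert og.expected_ibd_tract_bp(8) == pytest.approx(1.25e7)
    with pytest.raises(ValueError):
        og.expected_ibd_tract_bp(0)
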