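"""Segment partitioning, the b statistic, smoothing and origin assignment."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import origingwas as og
from origingwas.ancestry import (
    MIN_SEGMENT,
    infer_segment_origins,
    raw_origin_matrix,
    smooth_origin_probability,
)
from origingwas.experiments import ancestry_accuracy_experiment


def map_of(n, chrom=1):
    return pd.DataFrame({
        "chrom": chrom, "pos": np.arange(1, n + 1) * 1000,
        "id": [f"s{i}" for i in range(n)],
    })


def panel_from_rows(rows, n_animals=None):
    rows = np.asarray(rows, dtype=np.int8)
    n_animals = rows.shape[0] // 2
    return og.HaplotypePanel(
        snp_map=map_of(rows.shape[1]),
        haplotypes=rows,
        animal_ids=np.array([f"a{i}" for i in range(n_animals)], dtype=object),
    )


class TestDefineSegments:
    @pytest.mark.parametrize("n,expected", [
        (90, [30, 30, 30]),
        (92, [30, 31, 31]),
        (60, [30, 30]),
        (61, [30, 31]),
        (77, [30, 30, 17]),  # large remainder becomes a >=15-SNP terminal segment
        (74, [30, 44]),  # <15 terminal remainder merges backwards
    ])
    def test_partition_sizes(self, n, expected):
        segs = og.define_segments(map_of(n))
        assert [s.n_snps for s in segs] == expected

    def test_short_chromosome_single_segment_warns(self):
        with pytest.warns(UserWarning, match="undersized"):
            segs = og.define_segments(map_of(14))
        assert [s.n_snps for s in segs] == [14]

    def test_multi_chromosome_ordinals_and_coverage(self):
        sm = pd.concat([map_of(92), map_of(45, chrom=2)], ignore_index=True)
        segs = og.define_segments(sm)
        assert [s.ordinal for s in segs] == list(range(len(segs)))
        covered = np.concatenate([np.arange(s.first, s.last + 1) for s in segs])
        assert np.array_equal(np.sort(covered), np.arange(len(sm)))

    @given(n=st.integers(min_value=MIN_SEGMENT, max_value=2000))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_partition_property(self, n):
        segs = og.define_segments(map_of(n))
        sizes = [s.n_snps for s in segs]
        assert sum(sizes) == n
        assert all(MIN_SEGMENT <= s <= 44 for s in sizes)
        # non-terminal segments always 30 or 31
        assert all(s in (30, 31) for s in sizes[:-1])


class TestFrequencyTable:
    def test_counting_matches_hand_enumeration(self):
        # taurus haplotypes {s1, s1, s2, s3}; indicus {s1, s4, s4, s4}
        s1, s2, s3, s4 = [0] * 30, [1] * 30, [0, 1] * 15, [1, 0] * 15
        taur = panel_from_rows([s1, s1, s2, s3])
        indi = panel_from_rows([s1, s4, s4, s4])
        segs = og.define_segments(taur.snp_map)
        table = og.tabulate_haplotype_frequencies(taur, indi, segs)
        t = table.tables[0]
        key = np.asarray(s1, np.int8).tobytes()
        assert t[key] == (0.5, 0.25)
        assert t[np.asarray(s2, np.int8).tobytes()] == (0.25, 0.0)
        assert t[np.asarray(s4, np.int8).tobytes()] == (0.0, 0.75)

    def test_uniform_panel_gives_frequency_one(self):
        taur = panel_from_rows([[0] * 30] * 10)
        indi = panel_from_rows([[1] * 30] * 10)
        segs = og.define_segments(taur.snp_map)
        table = og.tabulate_haplotype_frequencies(taur, indi, segs)
        assert table.tables[0][np.zeros(30, np.int8).tobytes()] == (1.0, 0.0)

    def test_empty_reference_rejected(self):
        taur = panel_from_rows([[0] * 30] * 2)
        segs = og.define_segments(taur.snp_map)
        empty = og.HaplotypePanel(
            snp_map=taur.snp_map, haplotypes=np.empty((0, 30), np.int8),
            animal_ids=np.array([], dtype=object),
        )
        with pytest.raises(ValueError):
            og.tabulate_haplotype_frequencies(taur, empty, segs)


class TestRawB:
    @pytest.fixture()
    def toy_table(self):
        taur = panel_from_rows([[0] * 30, [0] * 30, [0] * 30, [1] * 30])
        indi = panel_from_rows([[1] * 30] * 8 + [[0] * 30] * 2)
        segs = og.define_segments(taur.snp_map)
        return og.tabulate_haplotype_frequencies(taur, indi, segs)

    def test_formula_cases(self, toy_table):
        # all-zero string: pBt = 0.75, pBi = 0.2 -> b = 0.2/0.95
        b = og.raw_origin_probability(toy_table, 0, np.zeros(30, np.int8))
        assert b == pytest.approx(0.2 / 0.95)
        # all-one string: pBt = 0.25, pBi = 0.8
        b = og.raw_origin_probability(toy_table, 0, np.ones(30, np.int8))
        assert b == pytest.approx(0.8 / 1.05)
        # unseen string -> missing
        b = og.raw_origin_probability(toy_table, 0, np.array([0, 1] * 15, np.int8))
        assert np.isnan(b)

    def test_direct_arithmetic(self, toy_table):
        # plant a string with (pBt, pBi) = (0.1, 0.4): b = 0.4/0.5 = 0.8
        key = np.array([1, 0] * 15, np.int8)
        toy_table.tables[0][key.tobytes()] = (0.1, 0.4)
        assert og.raw_origin_probability(toy_table, 0, key) == pytest.approx(0.8)
        # equal frequencies -> 0.5; absent from indicus -> 0.0
        toy_table.tables[0][key.tobytes()] = (0.25, 0.25)
        assert og.raw_origin_probability(toy_table, 0, key) == pytest.approx(0.5)
        toy_table.tables[0][key.tobytes()] = (0.2, 0.0)
        assert og.raw_origin_probability(toy_table, 0, key) == 0.0

    def test_symmetry_between_panels(self, toy_table):
        b = og.raw_origin_probability(toy_table, 0, np.zeros(30, np.int8))
        swapped = og.HaplotypeFrequencyTable(
            segments=toy_table.segments,
            tables=[{k: (pi, pt) for k, (pt, pi) in t.items()} for t in toy_table.tables],
            n_taurus_hap=toy_table.n_indicus_hap,
            n_indicus_hap=toy_table.n_taurus_hap,
        )
        b_sw = og.raw_origin_probability(swapped, 0, np.zeros(30, np.int8))
        assert b_sw == pytest.approx(1.0 - b)

    def test_length_mismatch_rejected(self, toy_table):
        with pytest.raises(ValueError, match="length"):
            og.raw_origin_probability(toy_table, 0, np.zeros(29, np.int8))


def segs_for(n_vals, chrom=1):
    from origingwas.ancestry import SegmentDefinition

    return [SegmentDefinition(chrom, i, i, i) for i in range(n_vals)]


class TestSmoothing:
    def test_constant_series_is_fixed_point(self):
        raw = np.full((1, 9), 0.9)
        sm = smooth_origin_probability(raw, segs_for(9), window=7)
        assert np.allclose(sm, 0.9)

    def test_center_window_average(self):
        raw = np.array([[1, 1, 1, 0, 1, 1, 1]], float)
        sm = smooth_origin_probability(raw, segs_for(7), window=7)
        assert sm[0, 3] == pytest.approx(6 / 7)

    def test_missing_values_skipped(self):
        raw = np.array([[0.2, np.nan, 0.4]])
        sm = smooth_origin_probability(raw, segs_for(3), window=3)
        assert sm[0, 1] == pytest.approx(0.3)

    def test_truncated_window_at_chromosome_start(self):
        series = np.array([[0.0, 0.6, 0.9, 0.3, 0.5, 0.7, 0.2, 0.8]])
        sm = smooth_origin_probability(series, segs_for(8), window=7)
        assert sm[0, 0] == pytest.approx(np.mean(series[0, :4]))

    def test_all_missing_window_falls_back_to_half(self):
        raw = np.full((1, 5), np.nan)
        sm = smooth_origin_probability(raw, segs_for(5), window=3)
        assert np.allclose(sm, 0.5)

    def test_window_respects_chromosome_boundaries(self):
        segs = segs_for(4) + segs_for(4, chrom=2)
        raw = np.concatenate([np.zeros((1, 4)), np.ones((1, 4))], axis=1)
        sm = smooth_origin_probability(raw, segs, window=7)
        assert np.allclose(sm[0, :4], 0.0) and np.allclose(sm[0, 4:], 1.0)

    @given(st.lists(
        st.one_of(st.floats(0, 1), st.just(float("nan"))), min_size=1, max_size=25,
    ))
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_matches_bruteforce_and_contracts(self, vals):
        raw = np.array([vals])
        k = raw.shape[1]
        sm = smooth_origin_probability(raw, segs_for(k), window=7)
        for j in range(k):
            window = raw[0, max(0, j - 3):min(k, j + 4)]
            finite = window[np.isfinite(window)]
            expected = finite.mean() if finite.size else 0.5
            assert sm[0, j] == pytest.approx(expected)
            if finite.size:  # smoothing is a contraction over the window
                assert finite.min() - 1e-12 <= sm[0, j] <= finite.max() + 1e-12


class TestClassification:
    @pytest.mark.parametrize("b,label", [(0.95, 1), (0.61, 1), (0.1, 0), (0.6, 0)])
    def test_threshold_rule(self, b, label):
        assert og.classify_origin(b) == label

    def test_assign_allele_origins_expands_segment_labels(self, small_sim):
        origins, aom = og.infer_ancestry(small_sim.taurus, small_sim.taurus,
                                         small_sim.indicus)
        # pure taurine animals classified taurine everywhere
        assert (aom.origins == 0).mean() > 0.99
        assert np.array_equal(aom.alleles, small_sim.taurus.haplotypes)

    def test_pure_indicine_fraction_near_one(self, small_sim):
        origins, _ = og.infer_ancestry(small_sim.indicus, small_sim.taurus,
                                       small_sim.indicus)
        _, per_group, _ = og.ancestry_fraction_report(
            origins, np.repeat("indicus", small_sim.indicus.n_animals)
        )
        assert per_group["mean"].iloc[0] > 0.97

    def test_composite_fraction_tracks_admixture(self):
        res = ancestry_accuracy_experiment(
            seed=17, n_ref=120, n_composite=60, admix_proportion=0.75,
            n_chromosomes=2,
        )
        assert res["group_indicine_fraction"] == pytest.approx(0.75, abs=0.05)

    def test_accuracy_monotone_in_divergence(self):
        accs = [
            ancestry_accuracy_experiment(
                seed=23, fst=f, n_ref=80, n_composite=40, n_chromosomes=2,
                snps_per_chromosome=600,
            )["allele_accuracy"]
            for f in (0.05, 0.2, 0.5)
        ]
        assert accs[0] <= accs[1] + 0.02 and accs[1] <= accs[2] + 0.02

    def test_accuracy_monotone_in_reference_size(self):
        accs = [
            ancestry_accuracy_experiment(
                seed=31, n_ref=n, n_composite=40, n_chromosomes=2,
                snps_per_chromosome=600,
            )["allele_accuracy"]
            for n in (20, 80, 250)
        ]
        assert accs[0] <= accs[1] + 0.02 and accs[1] <= accs[2] + 0.02


def test_toy_two_segment_oracle():
    """Brute-force enumeration of a 2-segment toy panel matches the pipeline."""
    rng = np.random.default_rng(99)
    taur_rows = rng.integers(0, 2, size=(8, 60)).astype(np.int8)
    indi_rows = rng.integers(0, 2, size=(6, 60)).astype(np.int8)
    taur = panel_from_rows(taur_rows)
    indi = panel_from_rows(indi_rows)
    segs = og.define_segments(taur.snp_map)
    assert len(segs) == 2
    table = og.tabulate_haplotype_frequencies(taur, indi, segs)
    raw = raw_origin_matrix(indi, table)
    for h in range(6):
        for j, seg in enumerate(segs):
            s = indi_rows[h, seg.first:seg.last + 1]
            p_bt = np.mean([np.array_equal(s, t[seg.first:seg.last + 1]) for t in taur_rows])
            p_bi = np.mean([np.array_equal(s, t[seg.first:seg.last + 1]) for t in indi_rows])
            expected = np.nan if p_bt + p_bi == 0 else p_bi / (p_bt + p_bi)
            if np.isnan(expected):
                assert np.isnan(raw[h, j])
            else:
                assert raw[h, j] == pytest.approx(expected)
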