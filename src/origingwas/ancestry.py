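"""Local ancestry of chromosome segments from reference haplotype frequencies.

Each chromosome is cut into non-overlapping segments of 30 or 31 consecutive
SNPs.  For the haplotype a given animal carries in a segment, the probability
that the segment is of indicine origin is

    b = pBi / (pBi + pBt)

where ``pBt`` and ``pBi`` are the frequencies of that segment haplotype in
the taurine and indicine reference panels.  A centered rolling average of
``b`` over seven segments exploits the length of recent admixture tracts;
segments are then labelled indicine when the smoothed value exceeds 0.6 and
taurine otherwise.  Combining the label with the A/B allele carried at each
SNP yields the four-class allele-origin coding (taurine A, taurine B,
indicine A, indicine B) that downstream association models use.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, HaplotypePanel

TAURINE, INDICINE = 0, 1
ORIGIN_NAMES = {TAURINE: "taurine", INDICINE: "indicine"}

#: minimum SNP count for a standalone terminal segment
MIN_SEGMENT = 15


@dataclass(frozen=True)
class SegmentDefinition:
    chromosome: int
    first: int  # global SNP index, inclusive
    last: int  # global SNP index, inclusive
    ordinal: int

    @property
    def n_snps(self) -> int:
        return self.last - self.first + 1

    @property
    def slice(self) -> slice:
        return slice(self.first, self.last + 1)


@dataclass
class HaplotypeFrequencyTable:
    """Per-segment frequencies of observed segment haplotypes in each panel."""

    segments: list[SegmentDefinition]
    tables: list[dict[bytes, tuple[float, float]]]  # string -> (pBt, pBi)
    n_taurus_hap: int
    n_indicus_hap: int


@dataclass
class SegmentOrigin:
    """Raw and smoothed b plus the hard origin call, per haplotype x segment."""

    segments: list[SegmentDefinition]
    raw_b: np.ndarray  # (n_hap, n_segments), NaN where unresolvable
    smoothed_b: np.ndarray  # (n_hap, n_segments)
    labels: np.ndarray  # int8, 0 taurine / 1 indicine


@dataclass
class AlleleOriginMatrix:
    """Every allele of every animal classified into one of four classes.

    ``alleles`` and ``origins`` are (2·n_animals, n_snps); rows are the
    ordered paternal/maternal haplotypes of the underlying panel.
    """

    alleles: np.ndarray
    origins: np.ndarray
    animal_ids: np.ndarray
    snp_map: pd.DataFrame


def define_segments(snp_map: pd.DataFrame, target_size: int = 30) -> list[SegmentDefinition]:
    """Partition each chromosome into segments of ``target_size``/+1 SNPs.

    When the SNP count is not divisible, the remainder is spread over the
    final segments (sizes 30/31).  On short chromosomes where that is not
    possible the terminal segment keeps the remainder if it has at least
    ``MIN_SEGMENT`` SNPs and is otherwise merged into the previous segment.
    A chromosome shorter than ``MIN_SEGMENT`` becomes a single undersized
    segment with a warning.
    """
    chrom = snp_map["chrom"].to_numpy()
    segs: list[SegmentDefinition] = []
    ordinal = 0
    start = 0
    for i in range(1, len(chrom) + 1):
        if i < len(chrom) and chrom[i] == chrom[start]:
            continue
        n = i - start
        c = int(chrom[start])
        sizes: list[int]
        k, r = divmod(n, target_size)
        if k == 0:
            if n < MIN_SEGMENT:
                warnings.warn(
                    f"chromosome {c} has only {n} SNPs; using one undersized segment"
                )
            sizes = [n]
        elif r == 0:
            sizes = [target_size] * k
        elif r <= k:
            sizes = [target_size] * (k - r) + [target_size + 1] * r
        elif r >= MIN_SEGMENT:
            sizes = [target_size] * k + [r]
        else:
            sizes = [target_size] * (k - 1) + [target_size + r]
        pos = start
        for s in sizes:
            segs.append(SegmentDefinition(c, pos, pos + s - 1, ordinal))
            ordinal += 1
            pos += s
        start = i
    return segs


def _segment_strings(panel: HaplotypePanel, seg: SegmentDefinition) -> list[bytes]:
    block = np.ascontiguousarray(panel.haplotypes[:, seg.slice])
    return [row.tobytes() for row in block]


def tabulate_haplotype_frequencies(
    panel_taurus: HaplotypePanel,
    panel_indicus: HaplotypePanel,
    segments: list[SegmentDefinition],
) -> HaplotypeFrequencyTable:
    """Count distinct segment haplotypes in each reference panel.

    Every string observed in either panel gets a frequency pair; a string
    absent from one panel has frequency 0 there.  Matching is exact.
    """
    if panel_taurus.n_animals == 0 or panel_indicus.n_animals == 0:
        raise ValueError("reference panels must be non-empty")
    n_t = panel_taurus.haplotypes.shape[0]
    n_i = panel_indicus.haplotypes.shape[0]
    tables = []
    for seg in segments:
        counts: dict[bytes, list[int]] = {}
        for s in _segment_strings(panel_taurus, seg):
            counts.setdefault(s, [0, 0])[0] += 1
        for s in _segment_strings(panel_indicus, seg):
            counts.setdefault(s, [0, 0])[1] += 1
        tables.append({k: (v[0] / n_t, v[1] / n_i) for k, v in counts.items()})
    return HaplotypeFrequencyTable(
        segments=segments, tables=tables, n_taurus_hap=n_t, n_indicus_hap=n_i
    )


def raw_origin_probability(
    freq_table: HaplotypeFrequencyTable, segment_ordinal: int, haplotype: bytes | np.ndarray
) -> float:
    """b = pBi / (pBi + pBt) for one segment haplotype; NaN if seen in neither panel."""
    seg = freq_table.segments[segment_ordinal]
    if not isinstance(haplotype, bytes):
        arr = np.ascontiguousarray(np.asarray(haplotype, dtype=np.int8))
        if arr.size != seg.n_snps:
            raise ValueError(
                f"haplotype length {arr.size} != segment length {seg.n_snps}"
            )
        haplotype = arr.tobytes()
    elif len(haplotype) != seg.n_snps:
        raise ValueError(
            f"haplotype length {len(haplotype)} != segment length {seg.n_snps}"
        )
    p_bt, p_bi = freq_table.tables[segment_ordinal].get(haplotype, (0.0, 0.0))
    tot = p_bt + p_bi
    if tot == 0.0:
        return float("nan")
    return p_bi / tot


def raw_origin_matrix(
    panel: HaplotypePanel, freq_table: HaplotypeFrequencyTable
) -> np.ndarray:
    """Raw b for every haplotype of ``panel`` at every segment."""
    n_hap = panel.haplotypes.shape[0]
    out = np.full((n_hap, len(freq_table.segments)), np.nan)
    for j, seg in enumerate(freq_table.segments):
        table = freq_table.tables[j]
        for h, s in enumerate(_segment_strings(panel, seg)):
            p_bt, p_bi = table.get(s, (0.0, 0.0))
            tot = p_bt + p_bi
            if tot > 0.0:
                out[h, j] = p_bi / tot
    return out


def smooth_origin_probability(
    raw_b: np.ndarray, segments: list[SegmentDefinition], window: int = 7
) -> np.ndarray:
    """Centered rolling mean of b along each chromosome, per haplotype.

    Missing raw values are skipped; the window truncates at chromosome ends.
    A position whose whole window is missing gets 0.5 (maximally uncertain,
    which the >0.6 rule resolves to taurine).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    raw_b = np.atleast_2d(np.asarray(raw_b, dtype=float))
    out = np.full_like(raw_b, np.nan)
    half = window // 2
    chroms = np.array([s.chromosome for s in segments])
    for c in np.unique(chroms):
        cols = np.flatnonzero(chroms == c)
        vals = raw_b[:, cols]
        finite = np.isfinite(vals)
        filled = np.where(finite, vals, 0.0)
        k = vals.shape[1]
        sums = np.zeros_like(vals)
        cnts = np.zeros_like(vals)
        for off in range(-half, half + 1):
            lo, hi = max(0, -off), min(k, k - off)
            if lo >= hi:
                continue
            sums[:, lo:hi] += filled[:, lo + off:hi + off]
            cnts[:, lo:hi] += finite[:, lo + off:hi + off]
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = sums / cnts
        sm[cnts == 0] = 0.5
        out[:, cols] = sm
    return out


def classify_origin(smoothed_b: np.ndarray | float, threshold: float = 0.6) -> np.ndarray:
    """Indicine iff smoothed b strictly exceeds the threshold (0.6 -> taurine)."""
    return (np.asarray(smoothed_b, dtype=float) > threshold).astype(np.int8)


def infer_segment_origins(
    panel: HaplotypePanel,
    freq_table: HaplotypeFrequencyTable,
    window: int = 7,
    threshold: float = 0.6,
) -> SegmentOrigin:
    raw = raw_origin_matrix(panel, freq_table)
    sm = smooth_origin_probability(raw, freq_table.segments, window)
    return SegmentOrigin(
        segments=freq_table.segments,
        raw_b=raw,
        smoothed_b=sm,
        labels=classify_origin(sm, threshold),
    )


def assign_allele_origins(panel: HaplotypePanel, origins: SegmentOrigin) -> AlleleOriginMatrix:
    """Expand per-segment labels to a per-SNP origin for every allele."""
    n_snps = panel.n_snps
    snp_origin = np.empty((origins.labels.shape[0], n_snps), dtype=np.int8)
    for j, seg in enumerate(origins.segments):
        snp_origin[:, seg.slice] = origins.labels[:, j][:, None]
    return AlleleOriginMatrix(
        alleles=panel.haplotypes,
        origins=snp_origin,
        animal_ids=panel.animal_ids,
        snp_map=panel.snp_map,
    )


def infer_ancestry(
    panel: HaplotypePanel,
    panel_taurus: HaplotypePanel,
    panel_indicus: HaplotypePanel,
    segment_size: int = 30,
    window: int = 7,
    threshold: float = 0.6,
) -> tuple[SegmentOrigin, AlleleOriginMatrix]:
    """Reference panels -> segment calls -> allele-origin matrix, in one step."""
    segments = define_segments(panel.snp_map, segment_size)
    table = tabulate_haplotype_frequencies(panel_taurus, panel_indicus, segments)
    origins = infer_segment_origins(panel, table, window, threshold)
    return origins, assign_allele_origins(panel, origins)


def ancestry_fraction_report(
    origins: SegmentOrigin,
    groups: np.ndarray,
    bins: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame, tuple[np.ndarray, np.ndarray]]:
    """Per-animal and per-group indicine segment fractions plus a b histogram.

    ``groups`` holds one label per animal (haplotype rows are paired).
    """
    frac_hap = origins.labels.mean(axis=1)
    frac_animal = 0.5 * (frac_hap[0::2] + frac_hap[1::2])
    per_animal = pd.DataFrame({"group": groups, "indicine_fraction": frac_animal})
    per_group = (
        per_animal.groupby("group", sort=True)["indicine_fraction"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    hist = np.histogram(origins.smoothed_b.ravel(), bins=bins, range=(0.0, 1.0))
    return per_animal, per_group, hist
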