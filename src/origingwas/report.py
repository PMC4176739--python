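"""Summaries of origin-aware association scans.

Covers the post-processing a multi-breed origin-aware study reports: the
expected-by-chance false discovery rate among declared-significant SNPs,
classification of each significant SNP by which of the three contrasts
(origin O, allele within taurus T, allele within indicus I) drive it, a
sign-consistency check for SNPs significant within both origins, selection
of the single most significant SNP per trait-by-chromosome, and inference
of which allele tracks the causal mutation from the winning best-variable
contrast.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

PATTERN_ORDER = ("OTI", "OT-", "O-I", "O--", "-TI", "-T-", "--I", "---")

#: the usual GWAS significance grid: suggestive, strong, genome-wide
DEFAULT_THRESHOLDS = (1e-4, 1e-6, 5e-8)


@dataclass(frozen=True)
class FdrSummary:
    trait: str
    subset: str
    threshold: float
    n_tested: int
    n_significant: int
    fdr_percent: int | None  # None when nothing is significant

    def is_na(self) -> bool:
        return self.fdr_percent is None


def estimate_fdr(
    n_significant: int,
    n_tested: int,
    threshold: float,
    trait: str = "",
    subset: str = "all",
    refined: bool = False,
) -> FdrSummary:
    """Expected-by-chance FDR among declared-significant SNPs, in percent.

    The estimate is ``100 * P * T / A`` (expected false positives over
    observed positives), truncated to an integer and capped at 100; it is
    undefined (None) when ``A = 0``.  ``refined=True`` uses
    ``P(1 - A/T) / ((A/T)(1 - P))``, which corrects for the true positives
    among the tested SNPs and differs negligibly at GWAS scale.
    """
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    if n_significant < 0 or n_significant > n_tested:
        raise ValueError("need 0 <= n_significant <= n_tested")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if n_significant == 0:
        pct: int | None = None
    else:
        if refined:
            a = n_significant / n_tested
            ratio = threshold * (1.0 - a) / (a * (1.0 - threshold))
        else:
            ratio = threshold * n_tested / n_significant
        pct = min(100, math.floor(100.0 * ratio))
    return FdrSummary(trait, subset, threshold, n_tested, n_significant, pct)


def fdr_table(
    results: pd.DataFrame,
    p_column: str = "p_x1",
    threshold: float = 1e-4,
    by: tuple[str, ...] = ("model", "subset"),
) -> pd.DataFrame:
    """FDR summary rows over testable SNPs, grouped by the given keys."""
    rows = []
    for keys, sub in results.groupby(list(by), sort=False):
        p = sub[p_column].to_numpy()
        tested = int(np.isfinite(p).sum())
        sig = int((p[np.isfinite(p)] < threshold).sum())
        summ = estimate_fdr(sig, tested, threshold) if tested else None
        rows.append(
            dict(zip(by, keys if isinstance(keys, tuple) else (keys,)))
            | {
                "threshold": threshold,
                "n_tested": tested,
                "n_significant": sig,
                "fdr_percent": summ.fdr_percent if summ else None,
            }
        )
    return pd.DataFrame(rows)


def classify_patterns(
    interaction_results: pd.DataFrame, threshold: float = 1e-4
) -> pd.DataFrame:
    """Label each SNP by which contrasts are significant: O, T, I.

    Uses the re-parameterised marginals: origin (x2 fitted with x6, x7),
    allele within taurus (x6) and allele within indicus (x7).  Only SNPs
    with at least one significant contrast receive a non-``---`` label.
    """
    df = interaction_results
    p_o = df["p_x2_r"].to_numpy() if "p_x2_r" in df else df["p_x2"].to_numpy()
    p_t = df["p_x6"].to_numpy()
    p_i = df["p_x7"].to_numpy()
    with np.errstate(invalid="ignore"):
        o = np.where(np.isfinite(p_o), p_o < threshold, False)
        t = np.where(np.isfinite(p_t), p_t < threshold, False)
        i = np.where(np.isfinite(p_i), p_i < threshold, False)
    label = np.array([
        ("O" if oo else "-") + ("T" if tt else "-") + ("I" if ii else "-")
        for oo, tt, ii in zip(o, t, i)
    ], dtype=object)
    out = df[["snp", "chrom", "pos"]].copy()
    out["sig_origin"] = o
    out["sig_taurine"] = t
    out["sig_indicine"] = i
    out["pattern"] = label
    return out


def pattern_counts(patterns: pd.DataFrame) -> pd.Series:
    """Counts per pattern label among SNPs with at least one significant contrast."""
    sig = patterns[patterns["pattern"] != "---"]
    return sig["pattern"].value_counts().reindex(PATTERN_ORDER[:-1], fill_value=0)


def sign_consistency_check(interaction_results: pd.DataFrame, threshold: float = 1e-4) -> pd.DataFrame:
    """Among SNPs significant within both origins, do b6 and b7 agree in sign?"""
    df = interaction_results
    both = (df["p_x6"] < threshold) & (df["p_x7"] < threshold)
    sub = df.loc[both.fillna(False), ["snp", "chrom", "pos", "b_x6", "b_x7"]].copy()
    sub["consistent"] = np.sign(sub["b_x6"]) == np.sign(sub["b_x7"])
    return sub.reset_index(drop=True)


def select_top_snps(
    best_results: pd.DataFrame, threshold: float = 1e-4, trait: str = "trait"
) -> pd.DataFrame:
    """Most significant SNP per chromosome passing the threshold.

    Avoids counting one QTL many times; p ties break on smaller position.
    """
    df = best_results[np.isfinite(best_results["p"]) & (best_results["p"] < threshold)]
    if df.empty:
        return df.assign(trait=pd.Series(dtype=object)).head(0)
    df = df.sort_values(["chrom", "p", "pos"], kind="mergesort")
    top = df.groupby("chrom", sort=True).head(1).copy()
    top.insert(0, "trait", trait)
    top["signed_t"] = top["estimate"] / top["se"]
    return top.reset_index(drop=True)


_VARIABLE_ALLELE = {
    "x4": ("taurus", "A"),
    "x5": ("indicus", "A"),
    "x6": ("taurus", "B"),
    "x7": ("indicus", "B"),
}


def infer_mutant_allele(top_record: pd.Series | dict) -> dict:
    """Which SNP allele tracks the causal mutation, from the best variable.

    A winning within-origin contrast (x4..x7) implicates that origin's
    allele: its within-origin frequency and signed effect approximate the
    frequency and effect of the linked QTL allele.  x1 (plain SNP) or x2
    (origin) winners are indeterminate; an x2 winner is the fixed-difference
    candidate pattern.
    """
    rec = dict(top_record)
    var = rec["best_variable"]
    if var in _VARIABLE_ALLELE:
        subspecies, allele = _VARIABLE_ALLELE[var]
        freq = rec["freq_B_taurine"] if subspecies == "taurus" else rec["freq_B_indicine"]
        if allele == "A":
            freq = 1.0 - freq
        return {
            "descriptor": f"{subspecies}_{allele}",
            "subspecies": subspecies,
            "allele": allele,
            "within_origin_freq": float(freq),
            "signed_effect": float(rec["estimate"]),
        }
    return {
        "descriptor": "shared/indeterminate",
        "subspecies": None,
        "allele": None,
        "within_origin_freq": float("nan"),
        "signed_effect": float(rec["estimate"]),
    }


def effect_frequency_plot_table(top_records: pd.DataFrame) -> pd.DataFrame:
    """Rows for a signed-t versus allele-frequency scatter of top SNPs."""
    if top_records.empty:
        return pd.DataFrame(columns=["trait", "subspecies", "frequency", "signed_t"])
    rows = []
    for _, rec in top_records.iterrows():
        info = infer_mutant_allele(rec)
        freq = info["within_origin_freq"]
        if not np.isfinite(freq):
            freq = rec["freq_B_all"]
        rows.append({
            "trait": rec.get("trait", "trait"),
            "subspecies": info["subspecies"] or "shared",
            "frequency": float(freq),
            "signed_t": float(rec["signed_t"]),
        })
    return pd.DataFrame(rows)


def plot_effect_frequency(table: pd.DataFrame, path: str) -> None:
    """Optional scatter artifact (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for sub, grp in table.groupby("subspecies"):
        ax.scatter(grp["frequency"], grp["signed_t"], label=sub, s=14, alpha=0.8)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("implicated allele frequency")
    ax.set_ylabel("signed t (estimate / SE)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
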