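"""Contrast coding of origin-classified SNP alleles.

Each single allele, classified as one of {taurine A, taurine B, indicine A,
indicine B}, is coded by seven 0/1 variables:

    x1  B allele (regardless of origin)
    x2  indicine origin (regardless of allele)
    x3  indicine B (x1 * x2, the origin-by-allele interaction)
    x4  taurine A        x5  indicine A
    x6  taurine B        x7  indicine B

so that x1 = x6 + x7, x2 = x5 + x7, x3 = x7 and exactly one of x4..x7 is 1.
Per animal the paternal and maternal codings are added, giving 0/1/2 counts.
Three allele-origin model parameterisations are supported: ``conventional``
fits x1 alone; ``interaction`` fits {x1, x2, x3}; ``reparam`` fits
{x2, x6, x7} (allele within each origin) and spans the same column space as
``interaction``; ``single:xk`` fits one variable at a time.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ancestry import INDICINE, TAURINE, AlleleOriginMatrix

VARIABLES = ("x1", "x2", "x3", "x4", "x5", "x6", "x7")

MODEL_COLUMNS = {
    "conventional": ("x1",),
    "interaction": ("x1", "x2", "x3"),
    "reparam": ("x2", "x6", "x7"),
}

#: variables tested one at a time in the best-variable scan (x3 == x7)
BEST_VARIABLE_SET = ("x1", "x2", "x4", "x5", "x6", "x7")


@dataclass(frozen=True)
class ContrastVector:
    x1: int
    x2: int
    x3: int
    x4: int
    x5: int
    x6: int
    x7: int

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3, self.x4, self.x5, self.x6, self.x7])


_TABLE = {
    ("taurine", "A"): ContrastVector(0, 0, 0, 1, 0, 0, 0),
    ("taurine", "B"): ContrastVector(1, 0, 0, 0, 0, 1, 0),
    ("indicine", "A"): ContrastVector(0, 1, 0, 0, 1, 0, 0),
    ("indicine", "B"): ContrastVector(1, 1, 1, 0, 0, 0, 1),
}


def encode_allele(origin: str, allele: str) -> ContrastVector:
    """Coding row for a single classified allele."""
    try:
        return _TABLE[(origin, allele)]
    except KeyError:
        raise ValueError(f"unknown allele class ({origin!r}, {allele!r})") from None


def encode_genotype(
    pair: tuple[tuple[str, str], tuple[str, str]]
) -> np.ndarray:
    """Component-wise sum of the paternal and maternal contrast vectors."""
    (o1, a1), (o2, a2) = pair
    return encode_allele(o1, a1).as_array() + encode_allele(o2, a2).as_array()


def _per_haplotype_variable(alleles: np.ndarray, origins: np.ndarray, var: str) -> np.ndarray:
    a = alleles
    o = origins
    if var == "x1":
        return a
    if var == "x2":
        return o
    if var in ("x3", "x7"):
        return a * o
    if var == "x4":
        return (1 - a) * (1 - o)
    if var == "x5":
        return (1 - a) * o
    if var == "x6":
        return a * (1 - o)
    raise ValueError(f"unknown variable {var!r}")


def variable_matrix(aom: AlleleOriginMatrix, var: str) -> np.ndarray:
    """Per-animal summed variable, (n_animals, n_snps) float.

    Missing alleles propagate to NaN for the whole genotype at that SNP
    (animal-wise deletion happens at fit time).
    """
    a = aom.alleles.astype(float)
    missing = aom.alleles < 0
    a[missing] = np.nan
    v = _per_haplotype_variable(a, aom.origins.astype(float), var)
    return v[0::2] + v[1::2]


@dataclass
class DesignMatrix:
    """SNP-term design columns for one SNP under one model tag."""

    snp_index: int
    model: str
    columns: tuple[str, ...]
    X: np.ndarray  # (n_animals, k)
    untestable: np.ndarray  # bool per column: constant over informative animals

    @property
    def all_untestable(self) -> bool:
        return bool(self.untestable.all())


def model_columns(model_tag: str) -> tuple[str, ...]:
    if model_tag in MODEL_COLUMNS:
        return MODEL_COLUMNS[model_tag]
    if model_tag.startswith("single:"):
        var = model_tag.split(":", 1)[1]
        if var not in VARIABLES:
            raise ValueError(f"unknown variable in model tag {model_tag!r}")
        return (var,)
    raise ValueError(f"unknown model tag {model_tag!r}")


def build_design(
    aom: AlleleOriginMatrix, snp_index: int, model_tag: str
) -> DesignMatrix:
    """Summed SNP-term columns for one SNP; constant columns are flagged.

    Flagged columns are kept in place (the fitter drops them and reduces
    the joint degrees of freedom) rather than raising: a monomorphic SNP is
    an untestable result, not an error.
    """
    cols = model_columns(model_tag)
    X = np.column_stack(
        [variable_matrix_single(aom, var, snp_index) for var in cols]
    )
    finite = np.isfinite(X).all(axis=1)
    untestable = np.array(
        [np.nanstd(X[finite, j]) == 0.0 if finite.any() else True for j in range(X.shape[1])]
    )
    return DesignMatrix(snp_index=snp_index, model=model_tag, columns=cols,
                        X=X, untestable=untestable)


def variable_matrix_single(aom: AlleleOriginMatrix, var: str, snp_index: int) -> np.ndarray:
    a = aom.alleles[:, snp_index].astype(float)
    a[aom.alleles[:, snp_index] < 0] = np.nan
    o = aom.origins[:, snp_index].astype(float)
    v = _per_haplotype_variable(a, o, var)
    return v[0::2] + v[1::2]
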