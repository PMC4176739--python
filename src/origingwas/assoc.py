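"""Mixed-model association testing under the origin-aware parameterisations.

The trait model is ``y = X beta + SNP terms + g + e`` with a polygenic
animal effect ``g ~ N(0, sigma_g^2 G)`` for a genomic relationship matrix G
and residual ``e ~ N(0, sigma_e^2 I)``.  Variance components are estimated
once by REML under the no-SNP null model; every SNP is then tested by
generalized least squares conditional on that covariance (two-stage,
EMMAX-style).  Rotating the data into the eigenbasis of G makes the per-SNP
work a weighted regression, so whole-genome scans are batched matrix algebra.

Per SNP the fitted block is one of: {x1} (conventional GWAS), {x1, x2, x3}
(interaction GWAS), {x2, x6, x7} (the equivalent re-parameterisation), or a
single variable (best-variable GWAS).  Marginal tests are Wald tests of each
coefficient in the joint fit; the joint test is a Wald chi-square on the
whole block with degrees of freedom equal to the number of testable columns.
Constant or collinear columns are dropped and flagged, never raised.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular as scipy_solve_triangular

from .ancestry import AlleleOriginMatrix
from .design import BEST_VARIABLE_SET, DesignMatrix, MODEL_COLUMNS, variable_matrix

_RANK_TOL = 1e-9


def vanraden_grm(dosage: np.ndarray) -> np.ndarray:
    """Centred-scaled cross-product genomic relationship matrix.

    ``dosage`` is the (n_animals, n_snps) B-allele count matrix; missing
    entries are mean-imputed for the purpose of relationship estimation.
    Monomorphic SNPs contribute nothing.
    """
    d = np.asarray(dosage, dtype=float)
    p = np.nanmean(d, axis=0) / 2.0
    d = np.where(np.isfinite(d), d, 2.0 * p[None, :])
    w = d - 2.0 * p[None, :]
    het = p * (1.0 - p)
    keep = het > 0
    denom = 2.0 * het[keep].sum()
    if denom <= 0:
        raise ValueError("no polymorphic SNPs to build a GRM from")
    w = w[:, keep]
    return (w @ w.T) / denom


@dataclass
class NullModelFit:
    """REML variance components and the cached covariance decomposition."""

    sigma_g2: float
    sigma_e2: float
    beta: np.ndarray
    n: int
    # transform caches
    sqrt_w: np.ndarray  # per-rotated-observation weight^(1/2)
    U: np.ndarray | None  # GRM eigenvectors (None => identity covariance)
    Q: np.ndarray  # orthonormal basis of the transformed covariates
    ty: np.ndarray  # transformed phenotype
    yr: np.ndarray  # ty residualized on Q
    X: np.ndarray  # original covariates
    y: np.ndarray
    grm: np.ndarray | None

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return 0.0 if tot == 0 else self.sigma_g2 / tot

    @property
    def sigma2(self) -> float:
        """Scale of the transformed-model residual variance."""
        return self.sigma_g2 + self.sigma_e2 if self.U is not None else self.sigma_e2

    def transform(self, m: np.ndarray) -> np.ndarray:
        """Whiten columns of ``m`` to the unit-variance rotated basis."""
        if self.U is None:
            return m * self.sqrt_w[:, None] if m.ndim == 2 else m * self.sqrt_w
        r = self.U.T @ m
        return r * self.sqrt_w[:, None] if m.ndim == 2 else r * self.sqrt_w


def fit_null_model(
    y: np.ndarray,
    covariates: np.ndarray,
    grm: np.ndarray | None = None,
    h2_grid: int = 40,
) -> NullModelFit:
    """REML fit of the no-SNP polygenic model.

    Profiles the total variance out of the restricted likelihood and
    optimises over ``h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)`` by a grid
    scan refined with bounded Brent search.  With ``grm=None`` the model
    reduces to ordinary least squares (sigma_g^2 = 0).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("covariates and phenotype disagree on n")
    n, q = X.shape
    if n <= q:
        raise ValueError("need more observations than covariates")
    if np.var(y) == 0:
        raise ValueError("phenotype has zero variance")

    decomposed = isinstance(grm, tuple)
    if grm is None:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sigma_e2 = float(resid @ resid) / (n - q)
        sqrt_w = np.ones(n)
        Q, _ = np.linalg.qr(X)
        yr = y - Q @ (Q.T @ y)
        return NullModelFit(0.0, sigma_e2, beta, n, sqrt_w, None, Q, y.copy(), yr,
                            X, y, None)

    if decomposed:  # precomputed (eigenvalues, eigenvectors)
        s, U = grm
        grm_full = U @ (s[:, None] * U.T)
    else:
        grm = np.asarray(grm, dtype=float)
        if grm.shape != (n, n) or not np.allclose(grm, grm.T, atol=1e-8):
            raise ValueError("GRM must be a symmetric n x n matrix")
        s, U = np.linalg.eigh(grm)
        grm_full = grm
    if s[0] < -1e-6 * max(1.0, s[-1]):
        raise ValueError("GRM is not positive semi-definite")
    s = np.clip(s, 0.0, None)
    ys = U.T @ y
    Xs = U.T @ X

    def neg_reml(h2: float) -> float:
        v = h2 * s + (1.0 - h2)
        w = 1.0 / v
        XtWX = (Xs * w[:, None]).T @ Xs
        beta = np.linalg.solve(XtWX, (Xs * w[:, None]).T @ ys)
        r = ys - Xs @ beta
        rss = float(w @ (r * r))
        sigma2 = rss / (n - q)
        _, logdet = np.linalg.slogdet(XtWX)
        return 0.5 * ((n - q) * np.log(sigma2) + np.log(v).sum() + logdet)

    grid = np.linspace(0.0, 0.99, h2_grid)
    vals = [neg_reml(h) for h in grid]
    i = int(np.argmin(vals))
    lo = grid[max(0, i - 1)]
    hi = grid[min(len(grid) - 1, i + 1)]
    if hi > lo:
        res = optimize.minimize_scalar(neg_reml, bounds=(lo, hi), method="bounded")
        h2 = float(res.x) if res.fun <= vals[i] else float(grid[i])
    else:
        h2 = float(grid[i])

    v = h2 * s + (1.0 - h2)
    w = 1.0 / v
    XtWX = (Xs * w[:, None]).T @ Xs
    beta = np.linalg.solve(XtWX, (Xs * w[:, None]).T @ ys)
    r = ys - Xs @ beta
    sigma2 = float(w @ (r * r)) / (n - q)
    sigma_g2 = h2 * sigma2
    sigma_e2 = (1.0 - h2) * sigma2

    sqrt_w = np.sqrt(w)
    ty = ys * sqrt_w
    Tx = Xs * sqrt_w[:, None]
    Q, _ = np.linalg.qr(Tx)
    yr = ty - Q @ (Q.T @ ty)
    return NullModelFit(sigma_g2, sigma_e2, beta, n, sqrt_w, U, Q, ty, yr, X, y,
                        grm_full)


@dataclass
class ScanResult:
    """Arrays over SNPs for one model; NaN marks untestable entries."""

    columns: tuple[str, ...]
    estimates: np.ndarray  # (m, k)
    se: np.ndarray  # (m, k)
    p_marginal: np.ndarray  # (m, k)
    joint_stat: np.ndarray  # (m,)
    joint_p: np.ndarray  # (m,)
    joint_df: np.ndarray  # (m,) int
    dropped: np.ndarray  # (m, k) bool


def _greedy_independent(gram: np.ndarray) -> np.ndarray:
    """Indices of a maximal well-conditioned leading subset of columns."""
    k = gram.shape[0]
    keep: list[int] = []
    for j in range(k):
        cand = keep + [j]
        sub = gram[np.ix_(cand, cand)]
        ev = np.linalg.eigvalsh(sub)
        if ev[0] > _RANK_TOL * max(ev[-1], 1.0):
            keep.append(j)
    return np.array(keep, dtype=int)


def gls_scan(null: NullModelFit, blocks: dict[str, np.ndarray]) -> ScanResult:
    """Test a block of SNP-term variables at every SNP.

    ``blocks`` maps variable name to an (n_animals, n_snps) matrix of
    per-animal summed codings.  SNPs with missing entries fall back to an
    exact per-SNP GLS with animal-wise deletion.
    """
    names = tuple(blocks)
    k = len(names)
    mats = [np.asarray(blocks[v], dtype=float) for v in names]
    n, m = mats[0].shape
    sigma2 = null.sigma2

    est = np.full((m, k), np.nan)
    se = np.full((m, k), np.nan)
    pm = np.full((m, k), np.nan)
    joint_stat = np.full(m, np.nan)
    joint_p = np.full(m, np.nan)
    joint_df = np.zeros(m, dtype=int)
    dropped = np.ones((m, k), dtype=bool)

    finite = np.ones(m, dtype=bool)
    for M in mats:
        finite &= np.isfinite(M).all(axis=0)
    complete = np.flatnonzero(finite)
    incomplete = np.flatnonzero(~finite)

    if complete.size:
        Zr = np.empty((k, n, complete.size))
        for a, M in enumerate(mats):
            Zt = null.transform(M[:, complete])
            Zr[a] = Zt - null.Q @ (null.Q.T @ Zt)
        yr = null.yr
        scale = (Zr**2).sum(axis=1)  # (k, mc)
        testable = scale > _RANK_TOL * n  # constant/covariate-collinear columns
        gram = np.einsum("anm,bnm->mab", Zr, Zr)
        rhs = np.einsum("anm,n->ma", Zr, yr)

        full = testable.all(axis=0)
        if k > 1:
            ev = np.linalg.eigvalsh(gram)
            full &= ev[:, 0] > _RANK_TOL * np.maximum(ev[:, -1], 1.0)
        else:
            full &= gram[:, 0, 0] > _RANK_TOL
        idx_full = np.flatnonzero(full)
        if idx_full.size:
            g = gram[idx_full]
            r = rhs[idx_full]
            b = np.linalg.solve(g, r[..., None])[..., 0]
            ginv = np.linalg.inv(g)
            var = sigma2 * np.einsum("mii->mi", ginv)
            cols = complete[idx_full]
            est[cols] = b
            se[cols] = np.sqrt(var)
            z2 = b**2 / var
            pm[cols] = stats.chi2.sf(z2, df=1)
            js = np.einsum("ma,ma->m", b, r) / sigma2
            joint_stat[cols] = js
            joint_df[cols] = k
            joint_p[cols] = stats.chi2.sf(js, df=k)
            dropped[cols] = False
        # degenerate SNPs: drop columns greedily
        for jj in np.flatnonzero(~full):
            col = complete[jj]
            avail = np.flatnonzero(testable[:, jj])
            if avail.size == 0:
                continue
            g_all = gram[jj][np.ix_(avail, avail)]
            keep_local = _greedy_independent(g_all)
            keep = avail[keep_local]
            if keep.size == 0:
                continue
            g = gram[jj][np.ix_(keep, keep)]
            r = rhs[jj][keep]
            b = np.linalg.solve(g, r)
            ginv = np.linalg.inv(g)
            var = sigma2 * np.diag(ginv)
            est[col, keep] = b
            se[col, keep] = np.sqrt(var)
            pm[col, keep] = stats.chi2.sf(b**2 / var, df=1)
            js = float(b @ r) / sigma2
            joint_stat[col] = js
            joint_df[col] = keep.size
            joint_p[col] = stats.chi2.sf(js, df=keep.size)
            dropped[col, keep] = False

    for col in incomplete:
        Z = np.column_stack([M[:, col] for M in mats])
        out = _fit_single_deleted(null, Z)
        if out is None:
            continue
        b, v, keep, js = out
        est[col, keep] = b
        se[col, keep] = np.sqrt(v)
        pm[col, keep] = stats.chi2.sf(b**2 / v, df=1)
        joint_stat[col] = js
        joint_df[col] = keep.size
        joint_p[col] = stats.chi2.sf(js, df=keep.size)
        dropped[col, keep] = False

    return ScanResult(names, est, se, pm, joint_stat, joint_p, joint_df, dropped)


def _fit_single_deleted(null: NullModelFit, Z: np.ndarray):
    """Exact GLS for one SNP with missing rows removed (slow path)."""
    rows = np.isfinite(Z).all(axis=1)
    if rows.sum() <= null.X.shape[1] + Z.shape[1]:
        return None
    Zs = Z[rows]
    Xs = null.X[rows]
    ys = null.y[rows]
    if null.grm is not None and null.sigma_g2 > 0:
        V = null.sigma_g2 * null.grm[np.ix_(rows.nonzero()[0], rows.nonzero()[0])]
        V[np.diag_indices_from(V)] += null.sigma_e2
        C = np.linalg.cholesky(V)
        Xw = scipy_solve_triangular(C, Xs, lower=True)
        Zw = scipy_solve_triangular(C, Zs, lower=True)
        yw = scipy_solve_triangular(C, ys, lower=True)
        sigma2 = 1.0  # variance absorbed into the whitening
    else:
        Xw, Zw, yw = Xs, Zs, ys
        sigma2 = null.sigma_e2
    Qs, _ = np.linalg.qr(Xw)
    Zr = Zw - Qs @ (Qs.T @ Zw)
    yr = yw - Qs @ (Qs.T @ yw)
    scale = (Zr**2).sum(axis=0)
    avail = np.flatnonzero(scale > _RANK_TOL * len(yw))
    if avail.size == 0:
        return None
    gram = Zr[:, avail].T @ Zr[:, avail]
    keep_local = _greedy_independent(gram)
    keep = avail[keep_local]
    if keep.size == 0:
        return None
    g = Zr[:, keep].T @ Zr[:, keep]
    r = Zr[:, keep].T @ yr
    b = np.linalg.solve(g, r)
    v = sigma2 * np.diag(np.linalg.inv(g))
    js = float(b @ r) / sigma2
    return b, v, keep, js


def test_snp(null: NullModelFit, design: DesignMatrix) -> dict:
    """Single-SNP convenience wrapper around :func:`gls_scan`."""
    res = gls_scan(
        null, {name: design.X[:, [j]] for j, name in enumerate(design.columns)}
    )
    out = {"snp_index": design.snp_index, "model": design.model,
           "joint_stat": float(res.joint_stat[0]), "joint_p": float(res.joint_p[0]),
           "joint_df": int(res.joint_df[0]),
           "untestable": bool(res.joint_df[0] == 0)}
    for j, name in enumerate(design.columns):
        out[f"b_{name}"] = float(res.estimates[0, j])
        out[f"se_{name}"] = float(res.se[0, j])
        out[f"p_{name}"] = float(res.p_marginal[0, j])
    return out


# ---------------------------------------------------------------------------
# whole-dataset scans


@dataclass
class GwasDataset:
    """Everything the three scans need, for one trait."""

    aom: AlleleOriginMatrix
    phenotypes: pd.DataFrame  # animal_id, group, y
    groups: np.ndarray
    grm: np.ndarray | None = None

    def __post_init__(self):
        if len(self.phenotypes) != len(self.groups):
            raise ValueError("phenotypes and groups disagree on n")

    def covariates(self, index: np.ndarray) -> np.ndarray:
        """Intercept plus breed-group indicators (first group as baseline)."""
        g = self.groups[index]
        levels = [lv for lv in np.unique(g)]
        cols = [np.ones(len(g))]
        for lv in levels[1:]:
            cols.append((g == lv).astype(float))
        return np.column_stack(cols)

    def subset_index(self, subset: str) -> np.ndarray:
        if subset == "all":
            return np.arange(len(self.groups))
        idx = np.flatnonzero(self.groups == subset)
        if idx.size == 0:
            raise ValueError(f"no animals in subset {subset!r}")
        return idx


def _null_for(ds: GwasDataset, index: np.ndarray) -> NullModelFit:
    y = ds.phenotypes["y"].to_numpy()[index]
    X = ds.covariates(index)
    grm = None
    if ds.grm is not None:
        grm = ds.grm[np.ix_(index, index)]
    return fit_null_model(y, X, grm)


def _result_frame(ds: GwasDataset, res: ScanResult, model: str, subset: str) -> pd.DataFrame:
    snp_map = ds.aom.snp_map
    out = pd.DataFrame({
        "snp": snp_map["id"].to_numpy(),
        "chrom": snp_map["chrom"].to_numpy(),
        "pos": snp_map["pos"].to_numpy(),
        "model": model,
        "subset": subset,
    })
    for j, name in enumerate(res.columns):
        out[f"b_{name}"] = res.estimates[:, j]
        out[f"se_{name}"] = res.se[:, j]
        out[f"p_{name}"] = res.p_marginal[:, j]
    out["joint_stat"] = res.joint_stat
    out["joint_p"] = res.joint_p
    out["joint_df"] = res.joint_df
    out["untestable"] = res.joint_df == 0
    return out


def run_conventional_gwas(
    ds: GwasDataset, subset: str = "all", null: NullModelFit | None = None
) -> pd.DataFrame:
    """Regression of phenotype on B-allele count (variable x1) per SNP."""
    index = ds.subset_index(subset)
    if null is None:
        null = _null_for(ds, index)
    x1 = variable_matrix(ds.aom, "x1")[index]
    res = gls_scan(null, {"x1": x1})
    return _result_frame(ds, res, "conventional", subset)


def run_interaction_gwas(
    ds: GwasDataset, null: NullModelFit | None = None
) -> pd.DataFrame:
    """Joint fit of allele, origin and interaction, in both parameterisations.

    Emits, per SNP, the {x1, x2, x3} coefficients/marginals, the equivalent
    {x2, x6, x7} re-parameterisation (suffix ``_r`` on its x2), and the joint
    statistics of both fits (identical up to numerical tolerance whenever
    both blocks are full rank).
    """
    index = ds.subset_index("all")
    if null is None:
        null = _null_for(ds, index)
    blocks1 = {v: variable_matrix(ds.aom, v)[index] for v in MODEL_COLUMNS["interaction"]}
    blocks2 = {v: variable_matrix(ds.aom, v)[index] for v in MODEL_COLUMNS["reparam"]}
    res1 = gls_scan(null, blocks1)
    res2 = gls_scan(null, blocks2)
    out = _result_frame(ds, res1, "interaction", "all")
    ren = {"x2": "x2_r"}
    for j, name in enumerate(res2.columns):
        nm = ren.get(name, name)
        out[f"b_{nm}"] = res2.estimates[:, j]
        out[f"se_{nm}"] = res2.se[:, j]
        out[f"p_{nm}"] = res2.p_marginal[:, j]
    out["joint_stat_reparam"] = res2.joint_stat
    out["joint_p_reparam"] = res2.joint_p
    out["joint_df_reparam"] = res2.joint_df
    return out


def _b_allele_frequencies(aom: AlleleOriginMatrix) -> pd.DataFrame:
    a = aom.alleles
    o = aom.origins
    called = a >= 0
    with np.errstate(invalid="ignore"):
        f_all = np.where(called, a, 0).sum(0) / called.sum(0)
        taur = called & (o == 0)
        indi = called & (o == 1)
        f_t = np.where(taur, a, 0).sum(0) / taur.sum(0)
        f_i = np.where(indi, a, 0).sum(0) / indi.sum(0)
    return pd.DataFrame({
        "freq_B_all": f_all, "freq_B_taurine": f_t, "freq_B_indicine": f_i,
    })


def run_best_variable_gwas(
    ds: GwasDataset, null: NullModelFit | None = None
) -> pd.DataFrame:
    """Fit each of x1, x2, x4, x5, x6, x7 alone; keep the most significant.

    Ties in p are broken by the fixed variable order.  The output carries
    the winning variable's effect, SE and p plus B-allele frequencies
    overall and within each inferred origin.
    """
    index = ds.subset_index("all")
    if null is None:
        null = _null_for(ds, index)
    per_var = {}
    for v in BEST_VARIABLE_SET:
        per_var[v] = gls_scan(null, {v: variable_matrix(ds.aom, v)[index]})
    m = ds.aom.alleles.shape[1]
    p_mat = np.column_stack([per_var[v].p_marginal[:, 0] for v in BEST_VARIABLE_SET])
    p_for_argmin = np.where(np.isfinite(p_mat), p_mat, np.inf)
    best_idx = np.argmin(p_for_argmin, axis=1)  # argmin takes the first on ties
    untestable = ~np.isfinite(p_mat).any(axis=1)
    best_var = np.array(BEST_VARIABLE_SET, dtype=object)[best_idx]
    best_var[untestable] = None
    rows = np.arange(m)
    est = np.column_stack([per_var[v].estimates[:, 0] for v in BEST_VARIABLE_SET])
    ses = np.column_stack([per_var[v].se[:, 0] for v in BEST_VARIABLE_SET])
    out = pd.DataFrame({
        "snp": ds.aom.snp_map["id"].to_numpy(),
        "chrom": ds.aom.snp_map["chrom"].to_numpy(),
        "pos": ds.aom.snp_map["pos"].to_numpy(),
        "model": "best_variable",
        "best_variable": best_var,
        "estimate": est[rows, best_idx],
        "se": ses[rows, best_idx],
        "p": p_mat[rows, best_idx],
        "untestable": untestable,
    })
    for v in BEST_VARIABLE_SET:
        out[f"p_{v}"] = per_var[v].p_marginal[:, 0]
        out[f"b_{v}"] = per_var[v].estimates[:, 0]
    out.loc[untestable, ["estimate", "se", "p"]] = np.nan
    freqs = _b_allele_frequencies(ds.aom)
    return pd.concat([out, freqs], axis=1)
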