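"""Desk-scale LD-score regression: SNP heritability and genetic correlation.

Under a polygenic model, the expected association chi-square of variant j in
a GWAS of n samples is E[χ²_j] = 1 + n·h²·ℓ_j/M, where ℓ_j is the variant's
LD score and M the number of variants the heritability h² is spread over, so
h² is M/n times the slope of a regression of χ² on ℓ.  For two traits, the
product of z-statistics regresses on ℓ with slope √(n₁n₂)·ρ_g/M, giving the
genetic covariance ρ_g and the genetic correlation
r_g = ρ_g/√(h²₁·h²₂); the cross-trait intercept absorbs sample overlap.

This module targets parameter recovery on synthetic inputs, not genome-scale
fidelity: regressions use the standard heteroskedasticity weights with a
single fixed-point update from an unweighted initial fit, and standard
errors come from a delete-one-block jackknife over contiguous variant blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError


@dataclass(frozen=True)
class LdscInput:
    """Per-variant LD scores and z-statistics for one or two traits."""

    table: pd.DataFrame  # columns: variant_id, ld_score, z1[, z2]
    n1: float
    m_variants: int
    n2: float | None = None
    n_overlap: float = 0.0
    pheno_corr: float = 0.0

    def __post_init__(self):
        if self.m_variants < len(self.table):
            raise ValidationError("m_variants must be >= number of records")
        if np.any(self.table["ld_score"].to_numpy() < 0):
            raise ValidationError("ld_score must be non-negative")
        if self.n1 <= 0 or (self.n2 is not None and self.n2 <= 0):
            raise ValidationError("sample sizes must be positive")


@dataclass(frozen=True)
class H2Result:
    h2: float
    intercept: float
    h2_se: float
    n_blocks: int


@dataclass(frozen=True)
class GenCorResult:
    h2_1: float
    h2_2: float
    intercept_1: float
    intercept_2: float
    cross_intercept: float
    rho_g: float
    rg: float
    rg_se: float
    rg_p: float
    flag: str | None = None


def _block_edges(J: int, n_blocks: int) -> np.ndarray:
    return np.linspace(0, J, n_blocks + 1).astype(int)


def _wls_with_blocks(ell, y, w, n_blocks):
    """Weighted fit of y on [1, ell] plus per-block normal-equation sums.

    Returns (coef, block_xtx, block_xty) where coef = [intercept, slope] and
    the block arrays allow delete-one-block refits by subtraction.
    """
    X = np.column_stack([np.ones_like(ell), ell])
    Xw = X * w[:, None]
    xtx_terms = np.einsum("ji,jk->jik", Xw, X)  # per-variant outer products
    xty_terms = Xw * y[:, None]
    edges = _block_edges(len(ell), n_blocks)
    block_xtx = np.add.reduceat(xtx_terms, edges[:-1], axis=0)
    block_xty = np.add.reduceat(xty_terms, edges[:-1], axis=0)
    xtx = block_xtx.sum(axis=0)
    xty = block_xty.sum(axis=0)
    coef = np.linalg.solve(xtx, xty)
    return coef, block_xtx, block_xty


def _check_size(J: int, n_blocks: int):
    if J < 2 * n_blocks:
        raise ValidationError(f"need at least {2 * n_blocks} variants for {n_blocks} jackknife blocks (got {J})")


def _h2_weights(ell, n, h2, M):
    return 1.0 / (2.0 * (1.0 + n * max(h2, 0.0) * ell / M) ** 2)


def _fit_h2(ell, z, n, M, n_blocks):
    chi2 = z**2
    slope0 = np.polyfit(ell, chi2, 1)[0]
    w = _h2_weights(ell, n, slope0 * M / n, M)
    coef, bxx, bxy = _wls_with_blocks(ell, chi2, w, n_blocks)
    return coef, bxx, bxy


def ldsc_h2(ld_scores, z, n, m_variants, n_blocks: int = 200) -> H2Result:
    """Single-trait SNP heritability with a block-jackknife standard error.

    An unweighted fit of χ² on ℓ seeds the heteroskedasticity weights
    1/(2(1 + n·h²·ℓ/M)²); one weighted refit gives the reported slope.
    """
    ell = np.asarray(ld_scores, dtype=float)
    z = np.asarray(z, dtype=float)
    _check_size(ell.size, n_blocks)
    coef, bxx, bxy = _fit_h2(ell, z, n, m_variants, n_blocks)
    h2 = float(coef[1] * m_variants / n)

    xtx, xty = bxx.sum(axis=0), bxy.sum(axis=0)
    loo = np.array(
        [np.linalg.solve(xtx - bxx[b], xty - bxy[b])[1] for b in range(n_blocks)]
    )
    h2_loo = loo * m_variants / n
    se = float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((h2_loo - h2_loo.mean()) ** 2)))
    return H2Result(h2=h2, intercept=float(coef[0]), h2_se=se, n_blocks=n_blocks)


def ldsc_rg(inp: LdscInput, n_blocks: int = 200) -> GenCorResult:
    """Bivariate LD-score regression: genetic covariance and correlation.

    Fits both single-trait regressions and the cross-trait regression of
    z₁z₂ on ℓ, then forms r_g = ρ_g/√(h²₁h²₂).  The standard error is a
    delete-one-block jackknife that recomputes all three regressions (with
    weights held fixed) for every deleted block.  A non-positive estimated
    heritability leaves r_g undefined and returns a flagged result rather
    than raising.
    """
    if inp.n2 is None or "z2" not in inp.table.columns:
        raise ValidationError("ldsc_rg needs z-statistics and a sample size for both traits")
    t = inp.table
    ell = t["ld_score"].to_numpy(dtype=float)
    z1 = t["z1"].to_numpy(dtype=float)
    z2 = t["z2"].to_numpy(dtype=float)
    n1, n2, M = float(inp.n1), float(inp.n2), float(inp.m_variants)
    _check_size(ell.size, n_blocks)

    coef1, bxx1, bxy1 = _fit_h2(ell, z1, n1, M, n_blocks)
    coef2, bxx2, bxy2 = _fit_h2(ell, z2, n2, M, n_blocks)
    h2_1 = float(coef1[1] * M / n1)
    h2_2 = float(coef2[1] * M / n2)

    y = z1 * z2
    rho0 = np.polyfit(ell, y, 1)[0] * M / np.sqrt(n1 * n2)
    wx = (1.0 + n1 * max(h2_1, 0.0) * ell / M) * (1.0 + n2 * max(h2_2, 0.0) * ell / M)
    w = 1.0 / (wx + (np.sqrt(n1 * n2) * rho0 * ell / M) ** 2)
    coefx, bxxx, bxyx = _wls_with_blocks(ell, y, w, n_blocks)
    rho_g = float(coefx[1] * M / np.sqrt(n1 * n2))

    base = dict(
        h2_1=h2_1,
        h2_2=h2_2,
        intercept_1=float(coef1[0]),
        intercept_2=float(coef2[0]),
        cross_intercept=float(coefx[0]),
        rho_g=rho_g,
    )
    if h2_1 <= 0 or h2_2 <= 0:
        return GenCorResult(**base, rg=np.nan, rg_se=np.nan, rg_p=np.nan,
                            flag="non-positive heritability: rg undefined")

    rg = rho_g / np.sqrt(h2_1 * h2_2)

    def _loo_slope(bxx, bxy, b):
        xtx = bxx.sum(axis=0) - bxx[b]
        xty = bxy.sum(axis=0) - bxy[b]
        return np.linalg.solve(xtx, xty)[1]

    rg_loo = np.empty(n_blocks)
    for b in range(n_blocks):
        h1_b = _loo_slope(bxx1, bxy1, b) * M / n1
        h2_b = _loo_slope(bxx2, bxy2, b) * M / n2
        rho_b = _loo_slope(bxxx, bxyx, b) * M / np.sqrt(n1 * n2)
        rg_loo[b] = rho_b / np.sqrt(h1_b * h2_b) if h1_b > 0 and h2_b > 0 else np.nan
    rg_loo = rg_loo[np.isfinite(rg_loo)]
    B = rg_loo.size
    rg_se = float(np.sqrt((B - 1) / B * np.sum((rg_loo - rg_loo.mean()) ** 2))) if B > 1 else np.nan
    rg_p = float(2.0 * stats.norm.sf(abs(rg / rg_se))) if rg_se and np.isfinite(rg_se) and rg_se > 0 else np.nan

    flag = None
    if abs(rg) > 1:
        flag = "rg outside [-1, 1] (not clamped)"
    return GenCorResult(**base, rg=float(rg), rg_se=rg_se, rg_p=rg_p, flag=flag)
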