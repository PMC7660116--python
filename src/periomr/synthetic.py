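"""Synthetic two-sample GWAS summary statistics and LDSC inputs with known truth.

The generator embodies the standard structural model for Mendelian
randomization with pleiotropy: each variant j has a true exposure effect γ_j
and a direct (pleiotropic) outcome effect α_j, and the true outcome effect is

    Γ_j = θ·γ_j + α_j.

Balanced pleiotropy has mean(α) = 0; directional pleiotropy a non-zero mean;
the InSIDE assumption is violated by giving (γ_j, α_j) a non-zero correlation
(Gaussian copula).  Observed effects add independent sampling noise:
γ̂_j ~ N(γ_j, σ_xj²) in the exposure sample, Γ̂_j ~ N(Γ_j, σ_yj²) in the
outcome sample.

Defaults mirror the study conditions of the periodontitis → cardiovascular
analysis: five unlinked instruments with exposure log-odds ratios around
ln 1.35, one palindromic variant in five, an exposure GWAS of 8,254 samples
and a stroke-scale binary outcome GWAS (44,221 cases / 739,957 controls),
with a null causal effect and no pleiotropy unless configured otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

_NON_PALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]
_PALINDROMIC_PAIRS = [("A", "T"), ("C", "G"), ("T", "A"), ("G", "C")]


@dataclass
class SyntheticConfig:
    """Generative parameters for a two-sample summary-statistics experiment.

    se mode: if ``se_from_sample_sizes`` is True, per-variant standard errors
    follow the binary-trait log-odds approximation
    se² = 1/(n·cf·(1−cf)·2q(1−q)); otherwise the fixed scales
    ``se_exposure_scale`` / ``se_outcome_scale`` are used directly.
    """

    n_variants: int = 5
    theta: float = 0.0
    gamma_mean: float = 0.30  # ~ ln 1.35, the instrument table's typical log-OR
    gamma_sd: float = 0.08
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    inside_corr: float = 0.0
    se_exposure_scale: float = 0.08  # typical Table-style instrument se
    se_outcome_scale: float = 0.012  # stroke-scale outcome GWAS precision
    se_from_sample_sizes: bool = False
    n_exposure: int = 8254
    exposure_case_fraction: float = 0.35
    n_outcome: int = 784178
    case_fraction: float = 0.0564  # 44,221 cases / 739,957 controls
    eaf_range: tuple = (0.1, 0.9)
    palindromic_fraction: float = 0.2
    seed: int | None = None

    def __post_init__(self):
        if self.n_variants < 1:
            raise ValidationError("n_variants must be >= 1")
        if self.pleiotropy_sd < 0:
            raise ValidationError("pleiotropy_sd must be >= 0")
        if not -1.0 <= self.inside_corr <= 1.0:
            raise ValidationError("inside_corr must lie in [-1, 1]")
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if not 0.0 <= self.palindromic_fraction <= 1.0:
            raise ValidationError("palindromic_fraction must lie in [0, 1]")


@dataclass
class TruthRecord:
    """Latent values behind one simulated dataset (for recovery tests)."""

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    big_gamma: np.ndarray
    se_exposure: np.ndarray
    se_outcome: np.ndarray
    seed: int
    config: dict = field(default_factory=dict)


def _binary_se(n, case_fraction, eaf):
    return np.sqrt(1.0 / (n * case_fraction * (1.0 - case_fraction) * 2.0 * eaf * (1.0 - eaf)))


def simulate_two_sample(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Draw exposure and outcome summary tables plus the latent truth record.

    Both tables use the canonical summary-statistics schema, share variant
    ids, alleles and frequencies, and report effects on the same
    (risk-increasing) allele; the configured fraction of variants gets
    palindromic allele pairs.  Variants whose latent γ_j is negative have the
    whole effect triple (γ, α, Γ) sign-flipped — the allele relabelling that
    risk-increasing orientation performs — so every true exposure effect is
    positive.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    J = cfg.n_variants

    # latent effects; Gaussian copula gives corr(gamma, alpha) = inside_corr
    zg = rng.standard_normal(J)
    za = cfg.inside_corr * zg + np.sqrt(1.0 - cfg.inside_corr**2) * rng.standard_normal(J)
    gamma = cfg.gamma_mean + cfg.gamma_sd * zg
    alpha = cfg.pleiotropy_mean + cfg.pleiotropy_sd * za
    flip = gamma < 0
    gamma, alpha = np.where(flip, -gamma, gamma), np.where(flip, -alpha, alpha)
    big_gamma = cfg.theta * gamma + alpha

    eaf = rng.uniform(*cfg.eaf_range, size=J)
    if cfg.se_from_sample_sizes:
        se_x = _binary_se(cfg.n_exposure, cfg.exposure_case_fraction, eaf)
        se_y = _binary_se(cfg.n_outcome, cfg.case_fraction, eaf)
    else:
        se_x = np.full(J, float(cfg.se_exposure_scale))
        se_y = np.full(J, float(cfg.se_outcome_scale))

    beta_x = rng.normal(gamma, se_x)
    beta_y = rng.normal(big_gamma, se_y)

    n_pal = int(round(cfg.palindromic_fraction * J))
    pal_idx = rng.choice(J, size=n_pal, replace=False)
    alleles = [_NON_PALINDROMIC_PAIRS[i] for i in rng.integers(len(_NON_PALINDROMIC_PAIRS), size=J)]
    for k, i in enumerate(pal_idx):
        alleles[i] = _PALINDROMIC_PAIRS[rng.integers(len(_PALINDROMIC_PAIRS))]

    def _table(beta, se, n_total, n_cases):
        return pd.DataFrame(
            {
                "variant_id": [f"rs{100000 + i}" for i in range(J)],
                "effect_allele": [a for a, _ in alleles],
                "other_allele": [b for _, b in alleles],
                "eaf": eaf,
                "beta": beta,
                "se": se,
                "p_value": 2.0 * stats.norm.sf(np.abs(beta / se)),
                "n_total": float(n_total),
                "n_cases": float(n_cases),
                "n_controls": float(n_total - n_cases),
            }
        )

    exposure = _table(beta_x, se_x, cfg.n_exposure, round(cfg.n_exposure * cfg.exposure_case_fraction))
    outcome = _table(beta_y, se_y, cfg.n_outcome, round(cfg.n_outcome * cfg.case_fraction))
    truth = TruthRecord(
        theta=cfg.theta,
        gamma=gamma,
        alpha=alpha,
        big_gamma=big_gamma,
        se_exposure=se_x,
        se_outcome=se_y,
        seed=cfg.seed,
        config=asdict(cfg),
    )
    return exposure, outcome, truth


def simulate_ldsc(
    m_variants: int,
    h2_1: float,
    h2_2: float,
    rg_true: float,
    n1: float,
    n2: float,
    seed: int,
    n_records: int | None = None,
    ld_score_mean: float = 50.0,
) -> pd.DataFrame:
    """Draw per-variant LD scores and bivariate z-statistics.

    LD scores come from a Gamma distribution with the requested mean (shape
    2); z-pairs are bivariate normal with Var(z_i) = 1 + n_i·h²_i·ℓ_j/M and
    Cov(z₁, z₂) = √(n₁n₂)·r_g·√(h²₁h²₂)·ℓ_j/M.  Returns a table with columns
    ``variant_id``, ``ld_score``, ``z1``, ``z2``.
    """
    for name, h2 in (("h2_1", h2_1), ("h2_2", h2_2)):
        if not 0.0 <= h2 <= 1.0:
            raise ValidationError(f"{name} must lie in [0, 1]")
    if not -1.0 <= rg_true <= 1.0:
        raise ValidationError("rg_true must lie in [-1, 1]")
    J = int(n_records if n_records is not None else m_variants)
    if J > m_variants:
        raise ValidationError("n_records cannot exceed m_variants")

    rng = np.random.default_rng(seed)
    ell = rng.gamma(shape=2.0, scale=ld_score_mean / 2.0, size=J)
    var1 = 1.0 + n1 * h2_1 * ell / m_variants
    var2 = 1.0 + n2 * h2_2 * ell / m_variants
    cov = np.sqrt(n1 * n2) * rg_true * np.sqrt(h2_1 * h2_2) * ell / m_variants
    disc = var2 - cov**2 / var1
    if np.any(disc < 0):
        j = int(np.argmin(disc))
        raise ValidationError(
            f"covariance not positive semi-definite at variant {j} "
            f"(h2_1={h2_1}, h2_2={h2_2}, rg={rg_true}, ld={ell[j]:.2f})"
        )
    u = rng.standard_normal(J)
    v = rng.standard_normal(J)
    z1 = np.sqrt(var1) * u
    z2 = cov / np.sqrt(var1) * u + np.sqrt(disc) * v
    return pd.DataFrame(
        {
            "variant_id": [f"rs{200000 + i}" for i in range(J)],
            "ld_score": ell,
            "z1": z1,
            "z2": z2,
        }
    )
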