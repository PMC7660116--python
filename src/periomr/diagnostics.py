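"""Per-variant influence diagnostics and the MR-PRESSO global heterogeneity test.

For each fitted MR regression (IVW through the origin, or MR-Egger with an
intercept), every variant gets a leverage from the weighted hat matrix, an
externally studentised residual (scaled by the leave-that-variant-out
estimate of the residual standard deviation) and a Cook's distance.  The
conventional flags are |studentised residual| > 3 for outliers and Cook's
distance > 4/n for high influence.

The MR-PRESSO global test compares the observed leave-one-out weighted
residual sum of squares against a parametric Monte-Carlo null in which every
variant's effects are redrawn from their sampling distributions around the
fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import MRResult, ivw
from .exceptions import ValidationError

SR_THRESHOLD = 3.0  # |externally studentised residual| above this -> outlier


def _design(pairs: pd.DataFrame, model: str):
    g = pairs["beta_exposure"].to_numpy(dtype=float)
    G = pairs["beta_outcome"].to_numpy(dtype=float)
    w = 1.0 / pairs["se_outcome"].to_numpy(dtype=float) ** 2
    sw = np.sqrt(w)
    if model == "IVW":
        X = (sw * g)[:, None]
    elif model == "MR-Egger":
        X = np.column_stack([sw, sw * g])
    else:
        raise ValidationError(f"unknown model {model!r}; expected 'IVW' or 'MR-Egger'")
    return X, sw * G


def regression_diagnostics(pairs: pd.DataFrame, model: str = "IVW") -> pd.DataFrame:
    """Leverages, studentised residuals and Cook's distances for one MR model.

    Needs J >= 3 variants for IVW and J >= 4 for MR-Egger so that a residual
    degree of freedom survives external studentisation.  Returns one row per
    variant with both internal and external studentised residuals, Cook's
    distance and the threshold flags (|SR| > 3, CD > 4/J).
    """
    J = len(pairs)
    p = 1 if model == "IVW" else 2
    minimum = p + 2
    if J < minimum:
        raise ValidationError(f"{model} diagnostics need at least {minimum} variants (got {J})")

    X, y = _design(pairs, model)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    h = np.einsum("ij,jk,ik->i", X, xtx_inv, X)  # hat-matrix diagonal
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (J - p)

    one_minus_h = 1.0 - h
    with np.errstate(invalid="ignore", divide="ignore"):
        internal = np.where(sigma2 > 0, resid / np.sqrt(sigma2 * one_minus_h), 0.0)
        sigma2_del = (rss - resid**2 / one_minus_h) / (J - p - 1)
        sigma2_del = np.maximum(sigma2_del, 0.0)
        external = np.where(sigma2_del > 0, resid / np.sqrt(sigma2_del * one_minus_h), 0.0)
        cooks = np.where(sigma2 > 0, internal**2 * h / (p * one_minus_h), 0.0)

    return pd.DataFrame(
        {
            "variant_id": pairs["variant_id"].to_numpy(),
            "model": model,
            "leverage": h,
            "studentised_residual": external,
            "internal_studentised_residual": internal,
            "cooks_distance": cooks,
            "outlier_flag": np.abs(external) > SR_THRESHOLD,
            "influential_flag": cooks > 4.0 / J,
        }
    )


def flag_summary(records: pd.DataFrame, target_variant: str) -> dict:
    """Tally, per variant, how many fitted models flagged it as influential.

    ``records`` concatenates diagnostic rows across outcomes and models and
    must contain ``variant_id`` and ``influential_flag``.  Returns the full
    per-variant tally plus the named variant's counts.
    """
    if records.empty:
        raise ValidationError("no diagnostic records supplied")
    tally = (
        records.groupby("variant_id")["influential_flag"]
        .agg(n_models="size", n_influential="sum")
        .reset_index()
    )
    tally["n_influential"] = tally["n_influential"].astype(int)
    tally["n_not_influential"] = tally["n_models"] - tally["n_influential"]
    if target_variant not in set(tally["variant_id"]):
        raise ValidationError(f"variant {target_variant!r} not present in diagnostic records")
    row = tally.set_index("variant_id").loc[target_variant]
    return {
        "per_variant": tally,
        "target_variant": target_variant,
        "n_models": int(row["n_models"]),
        "n_influential": int(row["n_influential"]),
        "n_not_influential": int(row["n_not_influential"]),
    }


@dataclass(frozen=True)
class PressoResult:
    """MR-PRESSO global test: observed RSS and its Monte-Carlo p-value."""

    rss_observed: float
    n_sim: int
    p_global: float
    seed: int


def _loo_theta(g, G, w):
    """Fixed-effects IVW slope with each variant deleted in turn (vectorised)."""
    num, den = np.sum(w * g * G), np.sum(w * g * g)
    return (num - w * g * G) / (den - w * g * g)


def presso_global(pairs: pd.DataFrame, n_sim: int = 1000, seed: int | None = None) -> PressoResult:
    """MR-PRESSO global heterogeneity (horizontal pleiotropy) test.

    The observed statistic is Σ_j w_j (Γ_j − θ̂_{−j} γ_j)² with θ̂_{−j} the
    fixed-effects IVW estimate excluding variant j.  Each null replicate
    redraws γ*_j ~ N(γ_j, σ_xj²) and Γ*_j ~ N(θ̂_{−j} γ_j, σ_Γj²) and
    recomputes the statistic (including its leave-one-out fits); the p-value
    uses the add-one estimator, so the smallest reportable value is
    1/(n_sim + 1).
    """
    J = len(pairs)
    if J < 4:
        raise ValidationError(f"MR-PRESSO global test needs at least 4 variants (got {J})")
    if n_sim < 100:
        raise ValidationError("n_sim must be at least 100")
    if seed is None:
        raise ValidationError("presso_global requires an explicit seed")

    g = pairs["beta_exposure"].to_numpy(dtype=float)
    G = pairs["beta_outcome"].to_numpy(dtype=float)
    sx = pairs["se_exposure"].to_numpy(dtype=float)
    sy = pairs["se_outcome"].to_numpy(dtype=float)
    w = 1.0 / sy**2

    theta_loo = _loo_theta(g, G, w)
    rss_obs = float(np.sum(w * (G - theta_loo * g) ** 2))

    rng = np.random.default_rng(seed)
    gs = rng.normal(g, sx, size=(n_sim, J))
    Gs = rng.normal(theta_loo * g, sy, size=(n_sim, J))
    num = np.sum(w * gs * Gs, axis=1, keepdims=True)
    den = np.sum(w * gs * gs, axis=1, keepdims=True)
    theta_star = (num - w * gs * Gs) / (den - w * gs * gs)
    rss_star = np.sum(w * (Gs - theta_star * gs) ** 2, axis=1)

    p = (1.0 + float(np.sum(rss_star >= rss_obs))) / (n_sim + 1.0)
    return PressoResult(rss_observed=rss_obs, n_sim=n_sim, p_global=p, seed=seed)


def exclude(pairs: pd.DataFrame, variant_ids) -> pd.DataFrame:
    """Drop the named variants from a harmonized-pairs table (sensitivity refits)."""
    if isinstance(variant_ids, str):
        variant_ids = [variant_ids]
    missing = set(variant_ids) - set(pairs["variant_id"])
    if missing:
        raise ValidationError(f"variants not in table: {sorted(missing)}")
    return pairs[~pairs["variant_id"].isin(set(variant_ids))].reset_index(drop=True)


def leave_one_out(pairs: pd.DataFrame, model: str = "random") -> pd.DataFrame:
    """IVW estimate with each variant excluded in turn (one row per exclusion)."""
    if len(pairs) < 2:
        raise ValidationError("leave-one-out needs at least 2 variants")
    rows = []
    for vid in pairs["variant_id"]:
        res: MRResult = ivw(exclude(pairs, vid), model=model)
        rows.append(
            {
                "excluded_variant": vid,
                "estimate": res.estimate,
                "se": res.se,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_value": res.p_value,
                "n_variants": res.n_variants,
            }
        )
    return pd.DataFrame(rows)
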