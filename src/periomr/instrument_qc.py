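"""Instrument strength, selection filters and post hoc power.

The strength of a genetic instrument set is summarised by the proportion of
exposure variance it explains (R²) and the expected first-stage F statistic

    F = ((N − K − 1) / K) · R² / (1 − R²),

with N the exposure-GWAS sample size and K the number of variants.  F well
above 10 indicates that weak-instrument bias is unlikely to be material.

Per-variant PVE is computed from summary statistics alone via the standard
approximation

    PVE = 2β²q(1−q) / (2β²q(1−q) + 2 N q(1−q) se²),

where q is the effect-allele frequency (the 2q(1−q) factors cancel
algebraically; the full form is kept for clarity and domain checking).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError


@dataclass(frozen=True)
class InstrumentStrength:
    """Summary of an instrument set's strength on the exposure."""

    n_exposure: float
    k_instruments: int
    r_squared: float
    f_statistic: float


@dataclass(frozen=True)
class PowerInput:
    """Inputs for a binary-outcome two-sided Wald power calculation.

    theta is the assumed causal log-odds ratio on the outcome per unit of the
    exposure; case_fraction is the proportion of cases in the outcome sample.
    """

    n_outcome: float
    case_fraction: float
    r_squared: float
    theta: float
    alpha: float = 0.05

    def __post_init__(self):
        if not 0 < self.case_fraction < 1:
            raise ValidationError("case_fraction must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if not 0 <= self.r_squared < 1:
            raise ValidationError("r_squared must lie in [0, 1)")
        if self.n_outcome <= 0:
            raise ValidationError("n_outcome must be positive")


def pve_from_summary(beta, eaf, se, n):
    """Proportion of exposure variance explained by one variant.

    Accepts scalars or aligned arrays.  Raises :class:`ValidationError` for
    monomorphic variants (eaf 0 or 1), non-positive se, or n <= 1.
    """
    beta = np.asarray(beta, dtype=float)
    q = np.asarray(eaf, dtype=float)
    se = np.asarray(se, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValidationError("eaf must lie strictly in (0, 1): monomorphic variant")
    if np.any(se <= 0):
        raise ValidationError("se must be > 0")
    if np.any(n <= 1):
        raise ValidationError("n must exceed 1")
    num = 2.0 * beta**2 * q * (1.0 - q)
    den = num + 2.0 * n * q * (1.0 - q) * se**2
    out = num / den
    return float(out) if out.ndim == 0 else out


def expected_f(n_exposure: float, k_instruments: int, r_squared: float) -> InstrumentStrength:
    """Expected F statistic of a K-variant instrument set.

    Raises :class:`ValidationError` when N <= K + 1 (no residual degrees of
    freedom) or R² outside [0, 1).
    """
    n, k, r2 = float(n_exposure), int(k_instruments), float(r_squared)
    if k < 1:
        raise ValidationError("k_instruments must be >= 1")
    if not 0 <= r2 < 1:
        raise ValidationError("r_squared must lie in [0, 1)")
    if n <= k + 1:
        raise ValidationError("n_exposure must exceed k_instruments + 1 (degenerate degrees of freedom)")
    f = (n - k - 1) / k * r2 / (1.0 - r2)
    return InstrumentStrength(n_exposure=n, k_instruments=k, r_squared=r2, f_statistic=f)


def select_instruments(
    candidates: pd.DataFrame,
    p_threshold: float = 5e-8,
) -> tuple[pd.DataFrame, list[str]]:
    """Apply the instrument-selection filters to a candidate table.

    Keeps candidates that reach genome-wide significance (``p_value`` strictly
    below ``p_threshold``) *and* are externally replicated (boolean
    ``replicated`` column), then keeps only the lead (smallest-p) candidate
    within each ``locus``.  Returns the selected table (sorted by locus, then
    p, then rsID, so the result is invariant to input ordering) and a
    rejection log naming the failing rule for each dropped candidate.
    """
    for col in ("p_value", "locus", "replicated"):
        if col not in candidates.columns:
            raise ValidationError(f"candidate table lacks required column {col!r}")
    df = candidates.copy()
    if df["replicated"].dtype == object:
        df["replicated"] = df["replicated"].astype(str).str.lower().isin(("true", "1", "yes"))

    log: list[str] = []
    sig = df["p_value"] < p_threshold
    rep = df["replicated"].astype(bool)
    keep = sig & rep
    for _, row in df[~keep].sort_values("variant_id").iterrows():
        rule = "significance" if not row["p_value"] < p_threshold else "replication"
        log.append(f"{row['variant_id']}: rejected ({rule} rule)")

    df = df[keep].sort_values(["locus", "p_value", "variant_id"], kind="mergesort")
    lead = df.groupby("locus", sort=True).head(1)
    for _, row in df[~df.index.isin(lead.index)].iterrows():
        log.append(f"{row['variant_id']}: rejected (lead-SNP rule, locus {row['locus']})")
    log.sort()
    if lead.empty:
        log.append("warning: no candidate passed all filters")
    return lead.reset_index(drop=True), log


def power_binary(inp: PowerInput) -> float:
    """Post hoc power for a two-sided Wald test of the causal effect.

    Normal approximation: the IVW estimate's standard error on a binary
    outcome is approximately 1/sqrt(n·R²·cf·(1−cf)), so

        power = Φ(|θ|/se − z_{1−α/2}) + Φ(−|θ|/se − z_{1−α/2}).

    Equals alpha at θ = 0 and increases monotonically in n, R² and |θ|.
    """
    z = stats.norm.ppf(1.0 - inp.alpha / 2.0)
    ncp = abs(inp.theta) * math.sqrt(
        inp.n_outcome * inp.r_squared * inp.case_fraction * (1.0 - inp.case_fraction)
    )
    return float(stats.norm.cdf(ncp - z) + stats.norm.cdf(-ncp - z))
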