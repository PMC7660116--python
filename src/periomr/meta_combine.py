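"""Fixed-effects inverse-variance meta-analysis of per-variant outcome effects.

Before Mendelian randomization, SNP-outcome associations estimated in two
independent studies of the same outcome (e.g. a consortium GWAS and a biobank
re-analysis) are pooled per variant with fixed-effects inverse-variance
weights.  Both inputs must already be harmonized to the same effect allele.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError


@dataclass(frozen=True)
class MetaResult:
    """Pooled effect for one variant plus a Cochran's Q heterogeneity note."""

    beta: float
    se: float
    q_statistic: float
    q_df: int
    q_p_value: float
    n_studies: int


def fixed_effect_meta(betas, ses) -> MetaResult:
    """Pool one variant's per-study effects with fixed-effects IVW weights.

    pooled beta = Σ(βᵢ/seᵢ²)/Σ(1/seᵢ²),  pooled se = sqrt(1/Σ(1/seᵢ²)).

    A single-study input is returned unchanged (Q = 0 on 0 df).
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValidationError("meta-analysis requires at least one study")
    if np.any(s <= 0) or np.any(~np.isfinite(s)):
        raise ValidationError("all standard errors must be finite and > 0")
    w = 1.0 / s**2
    pooled = float(np.sum(w * b) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    q = float(np.sum(w * (b - pooled) ** 2))
    df = int(b.size - 1)
    q_p = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    return MetaResult(beta=pooled, se=pooled_se, q_statistic=q, q_df=df, q_p_value=q_p, n_studies=int(b.size))


def meta_combine_tables(
    tables: list[pd.DataFrame],
    study_names: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Pool two or more harmonized outcome tables variant by variant.

    Each table needs columns ``variant_id``, ``effect_allele``,
    ``other_allele``, ``beta``, ``se`` on a shared effect allele.  A variant
    missing from some studies is carried from the studies that have it, with a
    logged flag.  Mismatched effect alleles for the same variant raise
    :class:`ValidationError` (harmonize first).

    Returns the pooled table (with a ``studies`` provenance column and
    Cochran's Q columns) and the log of missingness flags.
    """
    if not tables:
        raise ValidationError("need at least one outcome table")
    names = study_names or [f"study{i + 1}" for i in range(len(tables))]
    if len(names) != len(tables):
        raise ValidationError("study_names must match tables in length")

    order: list[str] = []
    seen = set()
    for t in tables:
        for vid in t["variant_id"]:
            if vid not in seen:
                seen.add(vid)
                order.append(vid)

    indexed = [t.set_index("variant_id") for t in tables]
    log: list[str] = []
    rows = []
    for vid in order:
        entries = [(name, t.loc[vid]) for name, t in zip(names, indexed) if vid in t.index]
        alleles = {(e["effect_allele"], e["other_allele"]) for _, e in entries}
        if len(alleles) > 1:
            raise ValidationError(f"{vid}: mismatched effect alleles across studies {sorted(alleles)}; harmonize first")
        if len(entries) < len(tables):
            missing = sorted(set(names) - {n for n, _ in entries})
            log.append(f"{vid}: absent from {', '.join(missing)}; pooled over {len(entries)} study(ies)")
        res = fixed_effect_meta([e["beta"] for _, e in entries], [e["se"] for _, e in entries])
        ea, oa = next(iter(alleles))
        rows.append(
            {
                "variant_id": vid,
                "effect_allele": ea,
                "other_allele": oa,
                "beta": res.beta,
                "se": res.se,
                "eaf": float(np.nanmean([e.get("eaf", np.nan) for _, e in entries])),
                "q_statistic": res.q_statistic,
                "q_df": res.q_df,
                "q_p_value": res.q_p_value,
                "studies": "+".join(n for n, _ in entries),
            }
        )
    return pd.DataFrame(rows), log
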