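"""Packaged fixtures: the five-SNP periodontitis instrument table and the
published per-variant influence diagnostics used for cross-checks."""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats


def _read(name: str) -> pd.DataFrame:
    with resources.files("periomr.data").joinpath(name).open("rt") as fh:
        return pd.read_csv(fh, sep="\t")


def load_periodontitis_instruments() -> pd.DataFrame:
    """The five periodontitis-associated instrument SNPs.

    One row per variant with rsID, locus, nearest gene, effect/other allele,
    effect-allele frequency, odds ratio with 95% CI, p-value, per-SNP
    proportion of variance explained (percent) and replication status.  The
    canonical ``beta``/``se`` columns are derived as beta = ln(OR) and
    se = (ln CI_high − ln CI_low)/(2·z_0.975).
    """
    df = _read("periodontitis_instruments.tsv")
    z = stats.norm.ppf(0.975)
    df["beta"] = np.log(df["or_point"])
    df["se"] = (np.log(df["or_ci_high"]) - np.log(df["or_ci_low"])) / (2.0 * z)
    df["n_total"] = np.nan
    df["n_cases"] = np.nan
    df["n_controls"] = np.nan
    return df


def load_influence_table() -> pd.DataFrame:
    """Published studentised residuals and Cook's distances.

    Six outcomes (coronary artery disease, any stroke, ischaemic stroke and
    three ischaemic subtypes) by two models (IVW, MR-Egger) by five variants.
    Cook's distances published censored as "<0.01" are stored as 0.005 (the
    censoring-interval midpoint) with ``cd_censored = True``; this cannot
    affect the CD > 4/5 influence rule.
    """
    return _read("influence_diagnostics.tsv")


def load_presso_pvalues() -> pd.DataFrame:
    """Published MR-PRESSO global-test p-values per outcome."""
    return _read("presso_global_pvalues.tsv")
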