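"""GWAS summary-statistic tables: reading, allele orientation and harmonization.

A summary-statistic dataset is held as a :class:`pandas.DataFrame` with one row
per variant and the canonical columns listed in :data:`VARIANT_COLUMNS`
(rsID, effect/other allele, effect-allele frequency, beta, se, p-value and
sample counts).  ``beta`` is on the log-odds scale for binary traits and in
trait units for continuous traits.

Two-sample Mendelian randomization requires the exposure and outcome effects
of each variant to be expressed on the same effect allele.  :func:`harmonize`
performs that alignment, including the frequency-based resolution of
palindromic (A/T, C/G) variants whose strand cannot be inferred from allele
labels alone.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, HarmonizationError, ValidationError

#: canonical schema; the first five columns are mandatory on read
VARIANT_COLUMNS = [
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "p_value",
    "n_total",
    "n_cases",
    "n_controls",
]

_REQUIRED = ["variant_id", "effect_allele", "other_allele", "beta", "se"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: allele pairs whose reverse-strand reading is indistinguishable
PALINDROMIC_SETS = (frozenset("AT"), frozenset("CG"))

#: harmonization outcomes recorded per intersected variant
ACTIONS = (
    "as-is",
    "allele-swap",
    "frequency-resolved",
    "dropped-ambiguous",
    "dropped-mismatch",
)


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is {A,T} or {C,G}."""
    return frozenset((effect_allele, other_allele)) in PALINDROMIC_SETS


def read_gwas_table(path, column_map: dict[str, str] | None = None, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited GWAS summary-statistics table.

    Parameters
    ----------
    path:
        File path (or open text buffer) of a tab- or comma-delimited table
        with a header row.  Lines starting with ``#`` are treated as comments
        (the synthetic-data writer stores its seed there).
    column_map:
        Mapping from canonical schema names (see :data:`VARIANT_COLUMNS`) to
        the column headers used in the file.  Unmapped canonical names are
        looked up under their own name; canonical columns absent from the
        file are filled with missing values (mandatory columns excepted).
    sep:
        Field delimiter; ``None`` infers tab vs comma from the header line.

    Returns
    -------
    pandas.DataFrame
        One row per data row, row order preserved, alleles upper-cased,
        missing numeric cells as NaN.

    Raises
    ------
    ConfigurationError
        If ``column_map`` names a header that is not in the file.
    ValidationError
        If any record has ``se <= 0``, a non-ACGT allele, ``eaf`` outside
        [0, 1] or ``p_value`` outside (0, 1]; the message lists the offending
        row numbers (1-based, excluding the header).
    """
    if sep is None:
        if hasattr(path, "read"):
            head = path.readline()
            path.seek(0)
        else:
            with open(path, "rt") as fh:
                head = fh.readline()
                while head.startswith("#"):
                    head = fh.readline()
        sep = "," if ("," in head and "\t" not in head) else "\t"

    raw = pd.read_csv(path, sep=sep, comment="#", dtype={0: str})
    column_map = dict(column_map or {})

    for canonical, header in column_map.items():
        if canonical not in VARIANT_COLUMNS:
            raise ConfigurationError(f"unknown canonical column {canonical!r}")
        if header not in raw.columns:
            raise ConfigurationError(
                f"column {header!r} (mapped from {canonical!r}) not found in file; "
                f"available: {list(raw.columns)}"
            )

    out = pd.DataFrame(index=raw.index)
    for canonical in VARIANT_COLUMNS:
        header = column_map.get(canonical, canonical)
        if header in raw.columns:
            out[canonical] = raw[header]
        elif canonical in _REQUIRED:
            raise ConfigurationError(f"mandatory column {canonical!r} missing from file")
        else:
            out[canonical] = np.nan

    out["variant_id"] = out["variant_id"].astype(str)
    for col in ("effect_allele", "other_allele"):
        out[col] = out[col].astype(str).str.upper()
    for col in ("eaf", "beta", "se", "p_value", "n_total", "n_cases", "n_controls"):
        out[col] = pd.to_numeric(out[col], errors="coerce")

    _validate(out)
    return out.reset_index(drop=True)


def _validate(df: pd.DataFrame) -> None:
    problems: list[str] = []
    bad_allele = (~df["effect_allele"].isin(list("ACGT"))) | (~df["other_allele"].isin(list("ACGT")))
    for row in df.index[bad_allele]:
        problems.append(f"row {row + 1}: allele not one of A/C/G/T")
    same = df["effect_allele"] == df["other_allele"]
    for row in df.index[same & ~bad_allele]:
        problems.append(f"row {row + 1}: effect and other allele identical")
    bad_se = df["se"].isna() | (df["se"] <= 0)
    for row in df.index[bad_se]:
        problems.append(f"row {row + 1}: se must be > 0")
    bad_eaf = df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1))
    for row in df.index[bad_eaf]:
        problems.append(f"row {row + 1}: eaf outside [0, 1]")
    bad_p = df["p_value"].notna() & ((df["p_value"] <= 0) | (df["p_value"] > 1))
    for row in df.index[bad_p]:
        problems.append(f"row {row + 1}: p_value outside (0, 1]")
    if problems:
        raise ValidationError("invalid GWAS records: " + "; ".join(problems))


def write_gwas_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a summary table as TSV, optionally with a leading ``#`` comment line."""
    buf = io.StringIO()
    if header_comment:
        buf.write(f"# {header_comment}\n")
    df.to_csv(buf, sep="\t", index=False)
    if hasattr(path, "write"):
        path.write(buf.getvalue())
    else:
        with open(path, "wt") as fh:
            fh.write(buf.getvalue())


def orient_risk_increasing(records: pd.DataFrame) -> pd.DataFrame:
    """Re-express every record so the effect allele is the risk-increasing allele.

    Records with ``beta < 0`` have their alleles swapped, beta negated and eaf
    complemented; records with ``beta >= 0`` are untouched (``beta == 0`` keeps
    the alleles as given — a documented tie-break).
    """
    out = records.copy()
    flip = out["beta"] < 0
    ea = out.loc[flip, "effect_allele"].copy()
    out.loc[flip, "effect_allele"] = out.loc[flip, "other_allele"]
    out.loc[flip, "other_allele"] = ea
    out.loc[flip, "beta"] = -out.loc[flip, "beta"]
    out.loc[flip, "eaf"] = 1.0 - out.loc[flip, "eaf"]
    return out


@dataclass
class HarmonizationReport:
    """Per-variant record of what :func:`harmonize` did.

    ``actions`` maps every variant in the exposure/outcome intersection to one
    of :data:`ACTIONS`; ``messages`` holds one human-readable line per variant
    that was dropped, swapped or frequency-resolved.
    """

    actions: dict[str, str] = field(default_factory=dict)
    messages: list[str] = field(default_factory=list)
    ambiguity_window: float = 0.08

    @property
    def counts(self) -> dict[str, int]:
        c = {a: 0 for a in ACTIONS}
        for a in self.actions.values():
            c[a] += 1
        return c

    @property
    def n_intersection(self) -> int:
        return len(self.actions)

    def __str__(self) -> str:  # structured text log, one line per event
        lines = [f"harmonization report (ambiguity window +/-{self.ambiguity_window:g} around 0.5)"]
        lines += self.messages or ["all variants aligned as-is"]
        lines.append("counts: " + ", ".join(f"{k}={v}" for k, v in self.counts.items()))
        return "\n".join(lines)


def _first_order_columns(pairs: pd.DataFrame) -> pd.DataFrame:
    """Populate the Wald-ratio columns (first-order delta-method se)."""
    pairs = pairs.copy()
    pairs["ratio_estimate"] = pairs["beta_outcome"] / pairs["beta_exposure"]
    pairs["ratio_se_first_order"] = pairs["se_outcome"] / pairs["beta_exposure"].abs()
    pairs["weight"] = 1.0 / pairs["ratio_se_first_order"] ** 2
    return pairs


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ambiguity_window: float = 0.08,
) -> tuple[pd.DataFrame, HarmonizationReport]:
    """Align outcome effects onto the exposure's (risk-increasing) effect alleles.

    The exposure table must already be oriented with
    :func:`orient_risk_increasing`.  Matching is by rsID only.  For
    non-palindromic variants, alleles are matched directly or after
    complementing (opposite strand); a label swap negates the outcome beta and
    complements its frequency.  Palindromic variants are resolved by allele
    frequency: kept in the given orientation when exposure and outcome
    frequencies fall on the same side of 0.5, sign-flipped when on opposite
    sides, and dropped when either frequency is missing or lies within
    ``ambiguity_window`` of 0.5.

    Returns
    -------
    (pairs, report)
        ``pairs`` has one row per retained variant with exposure and outcome
        effects on the shared allele plus the per-variant Wald ratio, its
        first-order standard error and inverse-variance weight;
        ``report`` records the action taken for every intersected variant.

    Raises
    ------
    HarmonizationError
        If the exposure and outcome share no variant ("no overlapping
        instruments").
    ValidationError
        If any retained exposure beta is not strictly positive (orientation
        precondition) or variant ids are duplicated within an input.
    """
    for name, df in (("exposure", exposure), ("outcome", outcome)):
        if df["variant_id"].duplicated().any():
            raise ValidationError(f"duplicate variant_id in {name} table")

    w = float(ambiguity_window)
    outc = outcome.set_index("variant_id")
    shared = [v for v in exposure["variant_id"] if v in outc.index]
    if not shared:
        raise HarmonizationError("no overlapping instruments")

    report = HarmonizationReport(ambiguity_window=w)
    rows = []
    expo = exposure.set_index("variant_id")
    for vid in shared:
        ex = expo.loc[vid]
        oc = outc.loc[vid]
        ea_x, oa_x = ex["effect_allele"], ex["other_allele"]
        ea_y, oa_y = oc["effect_allele"], oc["other_allele"]
        beta_y, se_y, eaf_y = oc["beta"], oc["se"], oc["eaf"]
        palindromic = is_palindromic(ea_x, oa_x)

        if palindromic:
            if frozenset((ea_y, oa_y)) != frozenset((ea_x, oa_x)):
                report.actions[vid] = "dropped-mismatch"
                report.messages.append(f"{vid}: palindromic allele sets differ -> dropped-mismatch")
                continue
            if ea_y != ea_x:  # align labels before the frequency check
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
            eaf_x = ex["eaf"]
            if (
                pd.isna(eaf_x)
                or pd.isna(eaf_y)
                or abs(eaf_x - 0.5) <= w
                or abs(eaf_y - 0.5) <= w
            ):
                report.actions[vid] = "dropped-ambiguous"
                report.messages.append(
                    f"{vid}: palindromic with eaf missing or within ({0.5 - w:g}, {0.5 + w:g}) -> dropped-ambiguous"
                )
                continue
            if (eaf_x - 0.5) * (eaf_y - 0.5) < 0:  # opposite strands
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
                report.messages.append(f"{vid}: palindromic, frequencies on opposite sides of 0.5 -> flipped")
            else:
                report.messages.append(f"{vid}: palindromic, frequencies concordant -> kept")
            action = "frequency-resolved"
        else:
            pair = (ea_y, oa_y)
            comp = (_COMPLEMENT.get(ea_y), _COMPLEMENT.get(oa_y))
            if pair == (ea_x, oa_x) or comp == (ea_x, oa_x):
                action = "as-is"
            elif pair == (oa_x, ea_x) or comp == (oa_x, ea_x):
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
                action = "allele-swap"
                report.messages.append(f"{vid}: outcome reported on the other allele -> allele-swap")
            else:
                report.actions[vid] = "dropped-mismatch"
                report.messages.append(f"{vid}: alleles irreconcilable ({ea_x}/{oa_x} vs {ea_y}/{oa_y}) -> dropped-mismatch")
                continue

        if not ex["beta"] > 0:
            raise ValidationError(
                f"{vid}: exposure beta must be > 0 after orientation (got {ex['beta']!r}); "
                "run orient_risk_increasing first"
            )
        report.actions[vid] = action
        rows.append(
            {
                "variant_id": vid,
                "effect_allele": ea_x,
                "other_allele": oa_x,
                "beta_exposure": float(ex["beta"]),
                "se_exposure": float(ex["se"]),
                "eaf_exposure": float(ex["eaf"]) if pd.notna(ex["eaf"]) else np.nan,
                "beta_outcome": float(beta_y),
                "se_outcome": float(se_y),
                "eaf_outcome": float(eaf_y) if pd.notna(eaf_y) else np.nan,
                "palindromic_flag": bool(palindromic),
                "harmonization_action": action,
            }
        )

    pairs = pd.DataFrame(
        rows,
        columns=[
            "variant_id",
            "effect_allele",
            "other_allele",
            "beta_exposure",
            "se_exposure",
            "eaf_exposure",
            "beta_outcome",
            "se_outcome",
            "eaf_outcome",
            "palindromic_flag",
            "harmonization_action",
        ],
    )
    if len(pairs):
        pairs = _first_order_columns(pairs)
    else:
        for col in ("ratio_estimate", "ratio_se_first_order", "weight"):
            pairs[col] = pd.Series(dtype=float)
    return pairs, report
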