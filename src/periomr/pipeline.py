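"""Config-driven orchestration of the full two-sample MR workflow.

One run takes an exposure instrument table and any number of outcome
datasets (each binary or continuous, possibly split over several studies to
be meta-combined), and produces per-outcome causal estimates on both the
per-unit and per-doubling scales, influence diagnostics, MR-PRESSO global
p-values, optional exclusion refits and optional LD-score genetic
correlations.  All stochastic stages take explicit seeds, and the rendered
report body is a pure function of (inputs, config, seeds).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from . import __version__
from .datasets import load_periodontitis_instruments
from .diagnostics import exclude, leave_one_out, presso_global, regression_diagnostics
from .estimators import egger, ivw, rescale_per_doubling, weighted_median
from .exceptions import ConfigurationError, PeriomrError
from .gencor import LdscInput, ldsc_rg
from .meta_combine import meta_combine_tables
from .summary_data import harmonize, orient_risk_increasing, read_gwas_table

DEFAULT_METHODS = ("IVW", "MR-Egger", "weighted-median")


@dataclass
class OutcomeSpec:
    name: str
    files: list
    binary: bool = True
    column_map: dict = field(default_factory=dict)


@dataclass
class RunConfig:
    """Everything one pipeline run depends on; loadable from YAML."""

    outcomes: list  # list[OutcomeSpec]
    exposure_file: str | None = None  # None -> packaged instrument table
    exposure_column_map: dict = field(default_factory=dict)
    methods: tuple = DEFAULT_METHODS
    ambiguity_window: float = 0.08
    n_boot: int = 10000
    presso_n_sim: int = 1000
    seed_bootstrap: int = 20200901
    seed_presso: int = 20200902
    sr_threshold: float = 3.0
    exclusions: list = field(default_factory=list)  # sensitivity refits
    gencor: dict | None = None  # {table: path, n1, n2, m_variants, n_blocks}
    output_dir: str | None = None

    def __post_init__(self):
        if not self.outcomes:
            raise ConfigurationError("at least one outcome is required")
        self.outcomes = [
            o if isinstance(o, OutcomeSpec) else OutcomeSpec(**o) for o in self.outcomes
        ]
        if self.sr_threshold <= 0:
            raise ConfigurationError("sr_threshold must be positive")
        unknown = set(self.methods) - set(DEFAULT_METHODS)
        if unknown:
            raise ConfigurationError(f"unknown methods: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "rt") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _load_exposure(config: RunConfig) -> pd.DataFrame:
    if config.exposure_file is None:
        return load_periodontitis_instruments()
    return read_gwas_table(config.exposure_file, column_map=config.exposure_column_map)


def _harmonized_pairs(exposure, spec: OutcomeSpec, window: float, events: list):
    """Harmonize each study file against the exposure, pooling if several."""
    per_study = []
    reports = []
    for path in spec.files:
        outcome = read_gwas_table(path, column_map=spec.column_map)
        pairs, report = harmonize(exposure, outcome, ambiguity_window=window)
        per_study.append(pairs)
        reports.append(report)
    if len(per_study) == 1:
        return per_study[0], reports

    tables = [
        p[["variant_id", "effect_allele", "other_allele", "beta_outcome", "se_outcome", "eaf_outcome"]]
        .rename(columns={"beta_outcome": "beta", "se_outcome": "se", "eaf_outcome": "eaf"})
        for p in per_study
    ]
    names = [f"{spec.name}:{i + 1}" for i in range(len(tables))]
    pooled, log = meta_combine_tables(tables, names)
    events.extend(f"[meta {spec.name}] {line}" for line in log)
    base = per_study[0].drop(columns=["beta_outcome", "se_outcome", "eaf_outcome",
                                      "ratio_estimate", "ratio_se_first_order", "weight"])
    merged = base.merge(
        pooled[["variant_id", "beta", "se", "eaf"]].rename(
            columns={"beta": "beta_outcome", "se": "se_outcome", "eaf": "eaf_outcome"}
        ),
        on="variant_id",
        how="inner",
    )
    merged["ratio_estimate"] = merged["beta_outcome"] / merged["beta_exposure"]
    merged["ratio_se_first_order"] = merged["se_outcome"] / merged["beta_exposure"].abs()
    merged["weight"] = 1.0 / merged["ratio_se_first_order"] ** 2
    return merged, reports


def _estimate(pairs, method, config: RunConfig, events, label):
    if method == "IVW":
        res = ivw(pairs)
        raw_phi = res.overdispersion_phi
        if raw_phi is not None and raw_phi == 1.0 and res.n_variants > 1:
            events.append(f"[{label}] IVW overdispersion truncated at 1")
        return res
    if method == "MR-Egger":
        res = egger(pairs)
        if res.overdispersion_phi == 1.0:
            events.append(f"[{label}] MR-Egger overdispersion truncated at 1")
        return res
    return weighted_median(pairs, n_boot=config.n_boot, seed=config.seed_bootstrap)


def _analyse(pairs, spec: OutcomeSpec, config: RunConfig, events, tag=""):
    label = spec.name + tag
    results = []
    for method in config.methods:
        try:
            per_unit = _estimate(pairs, method, config, events, label)
        except PeriomrError as exc:
            raise PeriomrError(f"stage 'estimate/{method}' failed for outcome {label!r}: {exc}") from exc
        per_doubling = rescale_per_doubling(per_unit, binary=spec.binary)
        for res in (per_unit, per_doubling):
            row = res.to_dict()
            row["outcome"] = label
            results.append(row)
    return results


def run_pipeline(config: RunConfig) -> dict:
    """Execute harmonize → meta-combine → estimate → rescale → diagnose →
    exclude-and-refit → gencor and return the structured run report."""
    events: list[str] = []
    exposure = orient_risk_increasing(_load_exposure(config))

    results_rows, diag_frames, presso_rows, loo_frames = [], [], [], []
    harmonization_logs = []
    for spec in config.outcomes:
        try:
            pairs, reports = _harmonized_pairs(exposure, spec, config.ambiguity_window, events)
        except PeriomrError as exc:
            raise PeriomrError(f"stage 'harmonize' failed for outcome {spec.name!r}: {exc}") from exc
        harmonization_logs.append((spec.name, [str(r) for r in reports]))

        results_rows.extend(_analyse(pairs, spec, config, events))

        for model in ("IVW", "MR-Egger"):
            try:
                d = regression_diagnostics(pairs, model=model)
            except PeriomrError as exc:
                events.append(f"[{spec.name}] diagnostics ({model}) skipped: {exc}")
                continue
            d.insert(0, "outcome", spec.name)
            diag_frames.append(d)

        try:
            pres = presso_global(pairs, n_sim=config.presso_n_sim, seed=config.seed_presso)
            presso_rows.append(
                {"outcome": spec.name, "rss_observed": pres.rss_observed,
                 "n_sim": pres.n_sim, "p_global": pres.p_global, "seed": pres.seed}
            )
        except PeriomrError as exc:
            events.append(f"[{spec.name}] MR-PRESSO skipped: {exc}")

        loo = leave_one_out(pairs)
        loo.insert(0, "outcome", spec.name)
        loo_frames.append(loo)

        if config.exclusions:
            reduced = exclude(pairs, config.exclusions)
            events.append(
                f"[{spec.name}] exclusion refit without {config.exclusions}: J={len(reduced)}"
            )
            results_rows.extend(_analyse(reduced, spec, config, events, tag=" (excl.)"))

    gencor_result = None
    if config.gencor is not None:
        gc = dict(config.gencor)
        table = pd.read_csv(gc["table"], sep="\t", comment="#")
        inp = LdscInput(table=table, n1=gc["n1"], n2=gc.get("n2"), m_variants=gc["m_variants"])
        gencor_result = ldsc_rg(inp, n_blocks=gc.get("n_blocks", 200))

    report = {
        "version": __version__,
        "config": _config_echo(config),
        "results": pd.DataFrame(results_rows),
        "diagnostics": pd.concat(diag_frames, ignore_index=True) if diag_frames else pd.DataFrame(),
        "presso": pd.DataFrame(presso_rows),
        "leave_one_out": pd.concat(loo_frames, ignore_index=True) if loo_frames else pd.DataFrame(),
        "harmonization": harmonization_logs,
        "gencor": gencor_result,
        "events": events,
    }
    if config.output_dir:
        _write_outputs(report, config.output_dir)
    return report


def _config_echo(config: RunConfig) -> dict:
    echo = asdict(config)
    echo["outcomes"] = [asdict(o) for o in config.outcomes]
    return echo


def render_report(report: dict) -> str:
    """Deterministic plain-text run report (no timestamps)."""
    lines = [f"periomr v{report['version']} run report", ""]
    lines.append("== configuration ==")
    lines.append(yaml.safe_dump(report["config"], sort_keys=True).rstrip())
    for section in ("results", "presso", "leave_one_out"):
        df = report[section]
        lines += ["", f"== {section} =="]
        lines.append(df.to_string(index=False) if len(df) else "(empty)")
    lines += ["", "== diagnostics =="]
    df = report["diagnostics"]
    lines.append(df.to_string(index=False) if len(df) else "(empty)")
    for name, logs in report["harmonization"]:
        lines += ["", f"== harmonization: {name} =="] + logs
    if report["gencor"] is not None:
        lines += ["", "== genetic correlation ==", str(report["gencor"])]
    lines += ["", "== events =="] + (report["events"] or ["(none)"])
    lines += [
        "",
        "note: p < 0.05 is described as significant, with no multiple-testing",
        "adjustment across outcomes or methods.",
    ]
    return "\n".join(lines) + "\n"


def _write_outputs(report: dict, output_dir: str) -> None:
    import os

    os.makedirs(output_dir, exist_ok=True)
    for section in ("results", "diagnostics", "presso", "leave_one_out"):
        df = report[section]
        if len(df):
            df.to_csv(os.path.join(output_dir, f"{section}.tsv"), sep="\t", index=False)
    with open(os.path.join(output_dir, "report.txt"), "wt") as fh:
        fh.write(render_report(report))
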