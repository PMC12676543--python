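"""End-to-end orchestration: thresholds -> classification -> PRR -> survival.

A single YAML config drives every stage. Re-running with the same config
and seed reproduces outputs byte for byte. Stages:

``simulate``   draw cohort, catalog and findings (when no inputs are given)
``thresholds`` compute and record the frequency cutoffs
``classify``   per-case etiology calls and the classification summary
``prr``        per-case PRRs, tiers, sensitivity sweep, treatability
``survive``    univariate screen plus stratified Cox comparisons
``report``     a markdown report mirroring the published table layouts
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .classify import classification_summary, classify_cases
from .io import (
    case_risk_frame,
    findings_from_frame,
    read_catalog,
    read_cohort,
    read_findings,
    write_catalog,
    write_findings,
    write_table,
)
from .prr import (
    TierRule,
    case_risks,
    format_prr,
    tier_sensitivity_sweep,
    treatability_summary,
)
from .simulate import GRiskSpec, SimulationConfig, simulate_cohort, \
    simulate_disorder_catalog, simulate_findings
from .survival import (
    DEFAULT_COMPARISONS,
    impute_covariates,
    stratified_reanalysis,
    univariate_screen,
)
from .thresholds import ThresholdParams, model_frequency_cutoff, \
    primary_cutoff, wilson_zero_upper

__all__ = ["RunManifest", "load_config", "run_pipeline", "render_report"]

STAGES = ("simulate", "thresholds", "classify", "prr", "survive", "report")

#: default floor pairs for the tier sensitivity sweep: (strong, very_strong)
DEFAULT_SWEEP_FLOORS = ((3.2, 50.0), (3.2, 99.0), (3.7, 50.0), (3.7, 99.0))


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = ""
    stages: dict[str, str] = field(default_factory=dict)  # stage -> status
    outputs: dict[str, str] = field(default_factory=dict)  # name -> path

    @property
    def complete(self) -> bool:
        return all(v == "done" for v in self.stages.values())

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


class ConfigError(ValueError):
    """The run configuration is invalid; message lists the fields."""


def load_config(path_or_dict: str | Path | Mapping[str, Any]) -> dict:
    if isinstance(path_or_dict, Mapping):
        cfg = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh) or {}
    cfg.setdefault("seed", 0)
    cfg.setdefault("thresholds", {})
    cfg.setdefault("tiers", {})
    cfg.setdefault("analysis", {})
    return cfg


def threshold_params(cfg: Mapping[str, Any]) -> ThresholdParams:
    return ThresholdParams(**cfg.get("thresholds", {}))


def tier_rule(cfg: Mapping[str, Any]) -> TierRule:
    return TierRule(**cfg.get("tiers", {}))


def _validate(cfg: Mapping[str, Any]) -> None:
    problems = []
    has_sim = "simulate" in cfg
    inputs = cfg.get("inputs", {})
    if not has_sim:
        for key in ("findings", "catalog"):
            if key not in inputs:
                problems.append(f"inputs.{key} required when simulate absent")
        if cfg.get("analysis", {}).get("factors") and "cohort" not in inputs:
            problems.append("inputs.cohort required for the survival stage")
    if problems:
        raise ConfigError("; ".join(problems))


def run_pipeline(
    config: str | Path | Mapping[str, Any], outdir: str | Path = "results"
) -> RunManifest:
    """Execute all stages; on a stage failure, later stages are skipped."""
    cfg = load_config(config)
    _validate(cfg)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = RunManifest(config=cfg, seed=seed, version=__version__)
    state: dict[str, Any] = {}

    for stage in STAGES:
        try:
            _STAGE_FUNCS[stage](cfg, state, out, manifest)
            manifest.stages[stage] = "done"
        except Exception as exc:  # mark and stop
            manifest.stages[stage] = f"failed: {exc}"
            for later in STAGES[STAGES.index(stage) + 1 :]:
                manifest.stages[later] = "skipped"
            break

    (out / "manifest.json").write_text(manifest.to_json())
    manifest.outputs["manifest"] = str(out / "manifest.json")
    return manifest


# ------------------------------------------------------------------ stages

def _stage_simulate(cfg, state, out: Path, manifest: RunManifest) -> None:
    sim_cfg = cfg.get("simulate")
    if sim_cfg is None:
        inputs = cfg["inputs"]
        state["findings"] = read_findings(inputs["findings"])
        state["catalog"] = read_catalog(inputs["catalog"])
        if "cohort" in inputs:
            state["cohort"] = read_cohort(inputs["cohort"])
        return
    sim_cfg = dict(sim_cfg)
    g_kwargs = dict(sim_cfg.pop("g_risk", {}) or {})
    sim = SimulationConfig(
        seed=int(cfg["seed"]),
        g_risk=GRiskSpec(**g_kwargs),
        **{k: v for k, v in sim_cfg.items() if k != "seed"},
    )
    cohort, truth = simulate_cohort(sim)
    catalog = simulate_disorder_catalog(sim)
    suid_ids = cohort.loc[cohort["outcome"] == "suid", "infant_id"].tolist()
    findings_df, case_truth = simulate_findings(suid_ids, catalog, sim)
    truth.case_truth = case_truth
    state.update(
        cohort=cohort,
        catalog=catalog,
        findings=findings_from_frame(findings_df),
        truth=truth,
        suid_ids=suid_ids,
    )
    cohort.to_csv(out / "cohort.csv", index=False)
    write_catalog(catalog, out / "catalog.tsv")
    write_findings(findings_df, out / "findings.tsv")
    write_table(case_truth, out / "case_truth.tsv")
    manifest.outputs.update(
        cohort=str(out / "cohort.csv"),
        catalog=str(out / "catalog.tsv"),
        findings=str(out / "findings.tsv"),
        case_truth=str(out / "case_truth.tsv"),
    )


def _stage_thresholds(cfg, state, out: Path, manifest: RunManifest) -> None:
    params = threshold_params(cfg)
    state["params"] = params
    df = pd.DataFrame(
        [
            {
                "model_cutoff": model_frequency_cutoff(params),
                "wilson_zero_bound": wilson_zero_upper(params.n_ref, params.crit),
                "primary_cutoff": primary_cutoff(params),
                "secondary_cutoff": params.f_secondary,
            }
        ]
    )
    write_table(df, out / "thresholds.tsv")
    manifest.outputs["thresholds"] = str(out / "thresholds.tsv")


def _stage_classify(cfg, state, out: Path, manifest: RunManifest) -> None:
    case_ids = state.get("suid_ids")
    if case_ids is None and "cohort" in state:
        case_ids = state["cohort"].loc[
            state["cohort"]["outcome"] == "suid", "infant_id"
        ].tolist()
    state["classifications"] = classify_cases(
        state["findings"], state["catalog"], state["params"], case_ids=case_ids
    )
    summary = classification_summary(state["classifications"], state["catalog"])
    write_table(summary.rename("value").rename_axis("metric").reset_index(),
                out / "classification_summary.tsv")
    manifest.outputs["classification_summary"] = str(
        out / "classification_summary.tsv"
    )


def _stage_prr(cfg, state, out: Path, manifest: RunManifest) -> None:
    rule = tier_rule(cfg)
    params = state["params"]
    risks = case_risks(state["classifications"], state["catalog"], params.P, rule)
    state["risks"] = risks
    risk_table = case_risk_frame(risks)
    state["case_risk_table"] = risk_table
    write_table(risk_table, out / "case_risk.tsv")

    floors = [
        tuple(x) for x in cfg["analysis"].get("sweep_floors", DEFAULT_SWEEP_FLOORS)
    ]
    sweep = tier_sensitivity_sweep(risks, floors, rule.ceiling)
    write_table(sweep, out / "tier_sweep.tsv")
    state["sweep"] = sweep

    used = {d for r in risks for d, _, _ in r.disorder_prrs}
    state["treatable_pct"] = treatability_summary(state["catalog"], used)
    manifest.outputs.update(
        case_risk=str(out / "case_risk.tsv"), tier_sweep=str(out / "tier_sweep.tsv")
    )


def _stage_survive(cfg, state, out: Path, manifest: RunManifest) -> None:
    if "cohort" not in state:
        state["effects"] = {}
        return
    analysis = cfg["analysis"]
    cohort = state["cohort"]
    if analysis.get("impute", True):
        cohort = impute_covariates(cohort, int(cfg["seed"]))
    factors = analysis.get("factors")
    if not factors:
        candidates = [
            c
            for c in cohort.columns
            if c not in ("infant_id", "outcome", "event_time")
            and not c.endswith("_imputed")
        ]
        screen = univariate_screen(
            cohort,
            candidates,
            alpha=analysis.get("alpha", 0.1),
            min_count=analysis.get("min_count", 5),
        )
        write_table(screen, out / "univariate_screen.tsv")
        manifest.outputs["univariate_screen"] = str(out / "univariate_screen.tsv")
        factors = screen.loc[screen["retained"], "factor"].tolist()
    tables = stratified_reanalysis(
        cohort, state["case_risk_table"], factors, DEFAULT_COMPARISONS
    )
    state["effects"] = tables
    for label, df in tables.items():
        path = out / f"effects_{label}.tsv"
        write_table(df, path)
        manifest.outputs[f"effects_{label}"] = str(path)


def _stage_report(cfg, state, out: Path, manifest: RunManifest) -> None:
    text = render_report(state)
    (out / "report.md").write_text(text)
    manifest.outputs["report"] = str(out / "report.md")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "thresholds": _stage_thresholds,
    "classify": _stage_classify,
    "prr": _stage_prr,
    "survive": _stage_survive,
    "report": _stage_report,
}


# ------------------------------------------------------------------ report

def render_report(state: Mapping[str, Any]) -> str:
    """Markdown report: classification shares, tiers, sweep, effect tables."""
    lines = ["# Genome x environment SUID risk analysis", ""]

    if "classifications" in state:
        summary = classification_summary(state["classifications"])
        lines += ["## Etiology classification", ""]
        n = summary["n_cases"]
        for cat in ("probable", "possible", "none"):
            lines.append(
                f"- {cat}: {summary[f'n_{cat}']} of {n} cases "
                f"({summary[f'pct_{cat}']}%)"
            )
        lines += [
            f"- retained findings: {summary['n_retained_findings']} in "
            f"{summary['n_distinct_loci']} distinct loci; "
            f"{summary['n_multi_disorder_cases']} cases with >1 disorder",
            "",
        ]

    if "risks" in state:
        risks = state["risks"]
        counts = {t: 0 for t in ("very_strong", "strong", "weak")}
        for r in risks:
            counts[r.tier] += 1
        n = len(risks)
        lines += ["## Genetic risk tiers", ""]
        for t, k in counts.items():
            pct = round(100 * k / n) if n else 0
            lines.append(f"- {t}: {k} cases ({pct}%)")
        if "treatable_pct" in state:
            lines.append(
                f"- disorders with preventative intervention: "
                f"{state['treatable_pct']}%"
            )
        lines.append("")

    if "sweep" in state:
        lines += ["## Tier threshold sensitivity", ""]
        lines.append(state["sweep"].to_string(index=False))
        lines.append("")

    for label, df in state.get("effects", {}).items():
        lines += [f"## Adjusted hazard ratios: {label}", ""]
        shown = df.copy()
        shown["ahr"] = [
            f"**{format_prr(v)}**" if sig and v == v else
            ("NA" if v != v else format_prr(v))
            for v, sig in zip(shown["ahr"], shown["significant"])
        ]
        lines.append(
            shown[["factor", "level", "ahr", "ci_low", "ci_high", "p"]]
            .round({"ci_low": 2, "ci_high": 2, "p": 4})
            .to_string(index=False)
        )
        lines.append("")
    return "\n".join(lines)
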