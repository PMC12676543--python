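"""Readers and writers for the pipeline's tabular formats.

Findings tables are TSV/CSV (delimiter inferred from the extension) with
header ``case_id,gene,disorder_id,variant_class,moi,moi_satisfied,f_obs,
phenotype_match,variant_type``; disorder catalogs are TSV with header
``disorder_id,name,birth_prevalence,p_death,infant_death_associated,
intervention_available,principal_organ``; cohorts are CSV with at least
``infant_id,outcome,event_time``. UTF-8, '.' decimal; scientific notation
accepted for frequencies.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .classify import DisorderProfile, GenotypeFinding
from .prr import CaseRisk

__all__ = [
    "read_findings",
    "write_findings",
    "read_catalog",
    "write_catalog",
    "read_cohort",
    "findings_from_frame",
    "case_risk_frame",
    "write_table",
]

_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n"}


def _sep(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _to_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"cannot parse boolean from {value!r}")


def findings_from_frame(df: pd.DataFrame) -> list[GenotypeFinding]:
    return [
        GenotypeFinding(
            case_id=str(r.case_id),
            gene=str(r.gene),
            disorder_id=str(r.disorder_id),
            variant_class=str(r.variant_class),
            moi=str(r.moi),
            moi_satisfied=_to_bool(r.moi_satisfied),
            f_obs=float(r.f_obs),
            phenotype_match=_to_bool(r.phenotype_match),
            variant_type=str(r.variant_type),
        )
        for r in df.itertuples(index=False)
    ]


def read_findings(path: str | Path) -> list[GenotypeFinding]:
    df = pd.read_csv(path, sep=_sep(path), dtype={"case_id": str})
    return findings_from_frame(df)


def write_findings(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep=_sep(path), index=False)


def read_catalog(path: str | Path) -> dict[str, DisorderProfile]:
    df = pd.read_csv(path, sep=_sep(path))
    catalog = {}
    for r in df.itertuples(index=False):
        catalog[str(r.disorder_id)] = DisorderProfile(
            disorder_id=str(r.disorder_id),
            name=str(r.name),
            birth_prevalence=float(r.birth_prevalence),
            p_death=float(r.p_death),
            infant_death_associated=_to_bool(r.infant_death_associated),
            intervention_available=_to_bool(r.intervention_available),
            principal_organ=str(r.principal_organ),
        )
    return catalog


def write_catalog(
    catalog: Mapping[str, DisorderProfile], path: str | Path
) -> None:
    rows = [
        {
            "disorder_id": p.disorder_id,
            "name": p.name,
            "birth_prevalence": p.birth_prevalence,
            "p_death": p.p_death,
            "infant_death_associated": p.infant_death_associated,
            "intervention_available": p.intervention_available,
            "principal_organ": p.principal_organ,
        }
        for p in catalog.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"infant_id": str})
    required = {"infant_id", "outcome", "event_time"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    bad = ~df["outcome"].isin(["suid", "other_death", "alive"])
    if bad.any():
        raise ValueError(
            f"unknown outcome values: {sorted(df.loc[bad, 'outcome'].unique())}"
        )
    alive = df["outcome"] == "alive"
    if (df.loc[alive, "event_time"] != 365).any():
        raise ValueError("infants alive at one year must have event_time 365")
    if ((df["event_time"] < 1) | (df["event_time"] > 365)).any():
        raise ValueError("event_time must be in [1, 365]")
    return df


def case_risk_frame(risks: Sequence[CaseRisk]) -> pd.DataFrame:
    """Per-case risk table: category, finding count, combined PRR, tier."""
    return pd.DataFrame(
        [
            {
                "case_id": r.case_id,
                "case_category": r.case_category,
                "n_disorders": len(r.disorder_prrs),
                "combined_prr": r.combined_prr,
                "tier": r.tier,
            }
            for r in risks
        ]
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
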