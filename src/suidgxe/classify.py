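"""Per-case etiology classification of whole-genome-sequencing findings.

Each retained WGS finding in a SUID case is a genotype in a gene associated
with a catalogued disorder known to cause infant death. A finding is called:

* **probable** — pathogenic/likely-pathogenic (P/LP) variant with genotype
  population frequency below the primary cutoff; or a VUS below the primary
  cutoff whose associated disorder's presentation matches death-certificate
  phenotypes (the phenotype upgrade);
* **possible** — a VUS below the primary cutoff without phenotype match, or
  a P/LP variant between the primary cutoff and the relaxed secondary
  cutoff (implying lower penetrance);
* **excluded** — anything else (frequency too high, mode of inheritance not
  satisfied, or disorder not associated with infant death).

A case's category is the best call over its findings. The module also hosts
the sequencing-run QC rule checker and the rule selecting, among the several
disorders a gene may cause, the one most likely to cause infant death.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .thresholds import ThresholdParams, primary_cutoff

__all__ = [
    "VARIANT_CLASSES",
    "ETIOLOGY_CALLS",
    "GenotypeFinding",
    "DisorderProfile",
    "CaseClassification",
    "QCReport",
    "NoEligibleDisorderError",
    "UnknownDisorderError",
    "qc_check",
    "select_disorder",
    "classify_finding",
    "classify_case",
    "classify_cases",
    "classification_summary",
    "demoted_findings",
]

VARIANT_CLASSES = ("P", "LP", "VUS")
VARIANT_TYPES = ("small", "structural")
ETIOLOGY_CALLS = ("probable", "possible", "excluded")
ORGAN_CATEGORIES = (
    "congenital-anomaly",
    "cardiac",
    "seizure",
    "immune",
    "respiratory",
    "other",
)


class NoEligibleDisorderError(ValueError):
    """No candidate disorder is associated with infant death."""


class UnknownDisorderError(KeyError):
    """Findings reference disorder ids absent from the catalog."""

    def __init__(self, ids: Sequence[str]):
        self.ids = sorted(set(ids))
        super().__init__(f"unknown disorder ids: {', '.join(self.ids)}")


@dataclass(frozen=True)
class GenotypeFinding:
    """One retained WGS finding in one SUID case."""

    case_id: str
    gene: str
    disorder_id: str
    variant_class: str  # P | LP | VUS
    moi: str  # AD | AR | XL
    moi_satisfied: bool
    f_obs: float  # genotype population frequency
    phenotype_match: bool = False
    variant_type: str = "small"

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(
                f"variant_class must be one of {VARIANT_CLASSES}, "
                f"got {self.variant_class!r}"
            )
        if self.variant_type not in VARIANT_TYPES:
            raise ValueError(
                f"variant_type must be one of {VARIANT_TYPES}, "
                f"got {self.variant_type!r}"
            )
        if not (0 <= self.f_obs <= 1):
            raise ValueError(f"f_obs must be in [0, 1], got {self.f_obs}")


@dataclass(frozen=True)
class DisorderProfile:
    """Catalog entry for a single-locus genetic disorder."""

    disorder_id: str
    name: str
    birth_prevalence: float
    p_death: float  # likelihood of infant death given the disorder
    infant_death_associated: bool
    intervention_available: bool
    principal_organ: str = "other"

    def __post_init__(self) -> None:
        if not (0 < self.birth_prevalence < 1):
            raise ValueError(
                f"birth_prevalence must be in (0, 1), got {self.birth_prevalence}"
            )
        if not (0 <= self.p_death <= 1):
            raise ValueError(f"p_death must be in [0, 1], got {self.p_death}")


@dataclass
class CaseClassification:
    """All findings of one case with their etiology calls."""

    case_id: str
    findings: list[tuple[GenotypeFinding, str]] = field(default_factory=list)

    @property
    def case_category(self) -> str:
        calls = [call for _, call in self.findings]
        if "probable" in calls:
            return "probable"
        if "possible" in calls:
            return "possible"
        return "none"

    @property
    def retained(self) -> list[tuple[GenotypeFinding, str]]:
        return [(f, c) for f, c in self.findings if c != "excluded"]


# ------------------------------------------------------------------ QC rules

#: (metric key, predicate description, rule)
_QC_RULES: dict[str, tuple[str, callable]] = {
    "q30_fraction": (">= 0.80", lambda v: v >= 0.80),
    "error_rate": ("<= 0.03", lambda v: v <= 0.03),
    "yield_gb": ("> 120", lambda v: v > 120),
    "duplicate_fraction": ("< 0.15", lambda v: v < 0.15),
    "aligned_fraction": ("> 0.98", lambda v: v > 0.98),
    "titv_ratio": ("in [2.0, 2.2]", lambda v: 2.0 <= v <= 2.2),
    "hom_het_ratio": ("in [0.40, 0.61]", lambda v: 0.40 <= v <= 0.61),
    "mim_cov10_fraction": ("> 0.90", lambda v: v > 0.90),
    "sex_match": ("is true", lambda v: bool(v)),
}


@dataclass
class QCReport:
    """Pass/fail per sequencing-QC metric; overall pass iff all rules pass."""

    values: dict[str, float]
    passed: dict[str, bool]

    @property
    def overall_pass(self) -> bool:
        return all(self.passed.values())

    @property
    def failed_metrics(self) -> list[str]:
        return [k for k, ok in self.passed.items() if not ok]


def qc_check(metrics: Mapping[str, float]) -> QCReport:
    """Apply the sequencing QC rules to one sample's metric map.

    Rules: Q30 fraction >= 0.80; error rate <= 0.03; yield > 120 Gb;
    duplicates < 0.15 (strict); aligned reads > 0.98; Ti/Tv in [2.0, 2.2];
    Hom/Het in [0.40, 0.61]; fraction of disease genes with 10x coverage
    > 0.90; reported and genomic sex match.
    """
    missing = [k for k in _QC_RULES if k not in metrics]
    if missing:
        raise KeyError(f"missing QC metrics: {', '.join(missing)}")
    values = {k: metrics[k] for k in _QC_RULES}
    passed = {k: bool(rule(values[k])) for k, (_, rule) in _QC_RULES.items()}
    return QCReport(values=values, passed=passed)


# ------------------------------------------------------- disorder selection

def select_disorder(
    gene: str, candidates: Sequence[DisorderProfile]
) -> DisorderProfile:
    """Pick, among a gene's disorders, the one most likely to cause SUID.

    Restricted to infant-death-associated candidates; ties on p_death break
    lexicographically by disorder id so the choice is deterministic.
    """
    eligible = [c for c in candidates if c.infant_death_associated]
    if not eligible:
        raise NoEligibleDisorderError(
            f"no infant-death-associated disorder among candidates for {gene}"
        )
    return min(eligible, key=lambda c: (-c.p_death, c.disorder_id))


# ------------------------------------------------------------ classification

def classify_finding(
    finding: GenotypeFinding,
    profile: DisorderProfile,
    params: ThresholdParams | None = None,
) -> str:
    """Call one finding probable / possible / excluded.

    The primary cutoff is the larger of the model and Wilson bounds; all
    frequency comparisons are strict, matching the published inequalities.
    """
    params = params or ThresholdParams()
    if finding.disorder_id != profile.disorder_id:
        raise ValueError(
            f"finding references {finding.disorder_id}, "
            f"profile is {profile.disorder_id}"
        )
    if not finding.moi_satisfied or not profile.infant_death_associated:
        return "excluded"

    f_primary = primary_cutoff(params)
    is_plp = finding.variant_class in ("P", "LP")

    if finding.f_obs < f_primary:
        if is_plp:
            return "probable"
        # VUS under the primary cutoff: phenotype overlap upgrades to probable
        return "probable" if finding.phenotype_match else "possible"
    if is_plp and finding.f_obs < params.f_secondary:
        return "possible"
    return "excluded"


def classify_case(
    findings: Sequence[GenotypeFinding],
    catalog: Mapping[str, DisorderProfile],
    params: ThresholdParams | None = None,
) -> CaseClassification:
    """Classify all findings of one case and derive its category."""
    case_ids = {f.case_id for f in findings}
    if len(case_ids) > 1:
        raise ValueError(f"findings span multiple cases: {sorted(case_ids)}")
    unknown = [f.disorder_id for f in findings if f.disorder_id not in catalog]
    if unknown:
        raise UnknownDisorderError(unknown)
    case_id = findings[0].case_id if findings else ""
    calls = [
        (f, classify_finding(f, catalog[f.disorder_id], params))
        for f in sorted(findings, key=lambda f: (f.disorder_id, f.gene))
    ]
    return CaseClassification(case_id=case_id, findings=calls)


def classify_cases(
    findings: Iterable[GenotypeFinding],
    catalog: Mapping[str, DisorderProfile],
    params: ThresholdParams | None = None,
    case_ids: Sequence[str] | None = None,
) -> list[CaseClassification]:
    """Group findings by case and classify each.

    ``case_ids`` optionally supplies the full case list so cases with no
    retained findings still appear (with category 'none').
    """
    by_case: dict[str, list[GenotypeFinding]] = {}
    for f in findings:
        by_case.setdefault(f.case_id, []).append(f)
    all_ids = list(case_ids) if case_ids is not None else sorted(by_case)
    out = []
    for cid in all_ids:
        fs = by_case.get(cid, [])
        cls = classify_case(fs, catalog, params)
        cls.case_id = cid
        out.append(cls)
    return out


def demoted_findings(
    classifications: Sequence[CaseClassification],
) -> list[GenotypeFinding]:
    """P/LP findings excluded solely because of frequency.

    These are diagnostic genotypes (e.g. Klinefelter-type findings) whose
    population frequency exceeds what SUID prevalence supports.
    """
    out = []
    for cls in classifications:
        for f, call in cls.findings:
            if (
                call == "excluded"
                and f.variant_class in ("P", "LP")
                and f.moi_satisfied
            ):
                out.append(f)
    return out


def classification_summary(
    classifications: Sequence[CaseClassification],
    catalog: Mapping[str, DisorderProfile] | None = None,
) -> pd.Series:
    """Counts and whole-percent shares over a set of case classifications.

    Reports per-category case counts/shares, retained findings, distinct
    loci, multi-disorder (G x G) cases, and, when a catalog is supplied,
    per-principal-organ counts over retained findings.
    """
    n = len(classifications)
    counts = {"probable": 0, "possible": 0, "none": 0}
    retained_total = 0
    loci: set[str] = set()
    multi = 0
    organs: dict[str, int] = {}
    for cls in classifications:
        counts[cls.case_category] += 1
        kept = cls.retained
        retained_total += len(kept)
        loci.update(f.gene for f, _ in kept)
        if len(kept) > 1:
            multi += 1
        if catalog is not None:
            for f, _ in kept:
                organ = catalog[f.disorder_id].principal_organ
                organs[organ] = organs.get(organ, 0) + 1

    def pct(k: int) -> int:
        return round(100 * k / n) if n else 0

    data = {
        "n_cases": n,
        "n_probable": counts["probable"],
        "pct_probable": pct(counts["probable"]),
        "n_possible": counts["possible"],
        "pct_possible": pct(counts["possible"]),
        "n_none": counts["none"],
        "pct_none": pct(counts["none"]),
        "n_genetic": counts["probable"] + counts["possible"],
        "pct_genetic": pct(counts["probable"] + counts["possible"]),
        "n_retained_findings": retained_total,
        "n_distinct_loci": len(loci),
        "n_multi_disorder_cases": multi,
    }
    for organ, k in sorted(organs.items()):
        data[f"n_organ_{organ}"] = k
    return pd.Series(data)
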