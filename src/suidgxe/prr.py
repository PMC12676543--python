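"""Prevalence risk ratios (PRR): quantifying genetic SUID risk per case.

The PRR of a disorder is its literature infant-mortality likelihood ``p``
divided by the population prevalence of SUID ``P``. A finding of *possible*
etiology carries the square root of the disorder's probable-etiology PRR
(expressivity discount). A case with several retained findings (G x G risk)
carries the product of its disorder PRRs, capped at the ceiling PRR that
represents 100% SUID risk. Cases are tiered:

* very strong — combined PRR above the very-strong floor (default 99);
  environmental factors are considered subsumed by the genetic cause;
* strong — combined PRR in [strong floor, very-strong floor] (default
  [3.7, 99]); designated environmental modifiers are retained;
* weak — everything below; all environmental factors are retained.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classify import CaseClassification, DisorderProfile

__all__ = [
    "TIERS",
    "TierRule",
    "CaseRisk",
    "prr_probable",
    "prr_possible",
    "combine_case_prr",
    "categorize_tier",
    "case_risk",
    "case_risks",
    "tier_sensitivity_sweep",
    "condition_e_factors",
    "treatability_summary",
    "format_prr",
]

TIERS = ("very_strong", "strong", "weak")

DEFAULT_P = 101 / 100_000


@dataclass(frozen=True)
class TierRule:
    """Tier floors and the PRR ceiling.

    ``very_strong_floor`` is exclusive (tier requires PRR > floor);
    ``strong_floor`` is inclusive. The ceiling, round(1/P) = 990 at the
    default SUID prevalence, is the PRR representing certain SUID.
    """

    very_strong_floor: float = 99.0
    strong_floor: float = 3.7
    ceiling: float = 990.0

    def __post_init__(self) -> None:
        if not (1 < self.strong_floor < self.very_strong_floor < self.ceiling):
            raise ValueError(
                "require 1 < strong_floor < very_strong_floor < ceiling, got "
                f"{self.strong_floor}, {self.very_strong_floor}, {self.ceiling}"
            )


@dataclass
class CaseRisk:
    """Quantified genetic risk for one case."""

    case_id: str
    disorder_prrs: list[tuple[str, str, float]] = field(default_factory=list)
    combined_prr: float = 1.0
    tier: str = "weak"
    case_category: str = "none"


def prr_probable(
    profile: DisorderProfile, P: float = DEFAULT_P, rule: TierRule | None = None
) -> float:
    """Probable-etiology PRR = p_death / P, capped at the ceiling."""
    if P <= 0:
        raise ValueError(f"P must be > 0, got {P}")
    rule = rule or TierRule()
    if profile.p_death == 0:
        warnings.warn(
            f"{profile.disorder_id}: p_death is 0; no excess risk "
            "representable, returning PRR 1",
            stacklevel=2,
        )
        return 1.0
    return min(profile.p_death / P, rule.ceiling)


def prr_possible(
    profile: DisorderProfile, P: float = DEFAULT_P, rule: TierRule | None = None
) -> float:
    """Possible-etiology PRR: square root of the probable PRR, then cap."""
    if P <= 0:
        raise ValueError(f"P must be > 0, got {P}")
    rule = rule or TierRule()
    if profile.p_death == 0:
        warnings.warn(
            f"{profile.disorder_id}: p_death is 0; no excess risk "
            "representable, returning PRR 1",
            stacklevel=2,
        )
        return 1.0
    # sqrt of the uncapped ratio, then cap (cap unreachable post-sqrt under
    # default parameters; order fixed for determinism)
    return min(math.sqrt(profile.p_death / P), rule.ceiling)


def combine_case_prr(
    disorder_prrs: Iterable[float], rule: TierRule | None = None
) -> float:
    """Product of the disorder PRRs, capped; empty input gives PRR 1."""
    rule = rule or TierRule()
    product = 1.0
    for x in disorder_prrs:
        if x <= 0:
            raise ValueError(f"PRRs must be > 0, got {x}")
        product *= x
    return min(product, rule.ceiling)


def categorize_tier(combined_prr: float, rule: TierRule | None = None) -> str:
    """Tier a combined PRR: weak < strong_floor <= strong <= very_strong_floor
    < very_strong."""
    rule = rule or TierRule()
    if combined_prr > rule.very_strong_floor:
        return "very_strong"
    if combined_prr >= rule.strong_floor:
        return "strong"
    return "weak"


def case_risk(
    classification: CaseClassification,
    catalog: Mapping[str, DisorderProfile],
    P: float = DEFAULT_P,
    rule: TierRule | None = None,
) -> CaseRisk:
    """Quantify one classified case: per-disorder PRRs, product, tier.

    Cases with no retained findings get combined PRR 1 and tier weak, so the
    tier partition covers every case.
    """
    rule = rule or TierRule()
    prrs: list[tuple[str, str, float]] = []
    for finding, call in classification.retained:
        profile = catalog[finding.disorder_id]
        value = (
            prr_probable(profile, P, rule)
            if call == "probable"
            else prr_possible(profile, P, rule)
        )
        prrs.append((finding.disorder_id, call, value))
    combined = combine_case_prr((v for _, _, v in prrs), rule)
    return CaseRisk(
        case_id=classification.case_id,
        disorder_prrs=prrs,
        combined_prr=combined,
        tier=categorize_tier(combined, rule),
        case_category=classification.case_category,
    )


def case_risks(
    classifications: Sequence[CaseClassification],
    catalog: Mapping[str, DisorderProfile],
    P: float = DEFAULT_P,
    rule: TierRule | None = None,
) -> list[CaseRisk]:
    return [case_risk(c, catalog, P, rule) for c in classifications]


def tier_sensitivity_sweep(
    risks: Sequence[CaseRisk],
    floors: Sequence[tuple[float, float]],
    ceiling: float = 990.0,
) -> pd.DataFrame:
    """Recompute tier shares for each (strong_floor, very_strong_floor) pair.

    Retiers the existing combined PRRs only — PRR values themselves do not
    depend on the floors. Output sorted by the floor pair, one row per pair,
    with per-tier counts and percentage shares.
    """
    n = len(risks)
    rows = []
    for strong_floor, very_strong_floor in sorted(floors):
        rule = TierRule(
            strong_floor=strong_floor,
            very_strong_floor=very_strong_floor,
            ceiling=ceiling,
        )
        counts = {t: 0 for t in TIERS}
        for r in risks:
            counts[categorize_tier(r.combined_prr, rule)] += 1
        row = {
            "strong_floor": strong_floor,
            "very_strong_floor": very_strong_floor,
        }
        for t in TIERS:
            row[f"n_{t}"] = counts[t]
            row[f"pct_{t}"] = 100 * counts[t] / n if n else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def condition_e_factors(
    tier: str,
    e_factors: Sequence[str],
    modifiers: Sequence[str] = (),
) -> tuple[set[str], set[str]]:
    """Tier-dependent conditioning of environmental factors.

    Returns (retained, subsumed). Very strong genetic risk subsumes every
    environmental factor; strong risk retains only the designated causal
    modifiers; weak risk retains everything.
    """
    factors = set(e_factors)
    mods = set(modifiers)
    if not mods <= factors:
        raise ValueError(
            f"modifiers not among e_factors: {sorted(mods - factors)}"
        )
    if tier == "very_strong":
        return set(), factors
    if tier == "strong":
        return mods, factors - mods
    if tier == "weak":
        return factors, set()
    raise ValueError(f"unknown tier {tier!r}; expected one of {TIERS}")


def treatability_summary(
    catalog: Mapping[str, DisorderProfile], used_disorders: Iterable[str]
) -> int:
    """Whole-percent share of used disorders with an available intervention."""
    used = set(used_disorders)
    unknown = used - set(catalog)
    if unknown:
        raise KeyError(f"disorders not in catalog: {sorted(unknown)}")
    if not used:
        return 0
    flagged = sum(1 for d in used if catalog[d].intervention_available)
    return round(100 * flagged / len(used))


def format_prr(value: float) -> str:
    """Display rounding used in reports: integers at >= 100, else 1 decimal."""
    if value >= 100:
        return str(round(value))
    return f"{value:.1f}"
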