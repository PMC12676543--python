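"""Cohort survival analysis of environmental SUID risk factors.

The cohort is every live birth over the study window, one row per infant,
with maternal/pregnancy/infant covariates, an outcome class (``suid``,
``other_death``, ``alive``) and an event time in days of life (1-365). The
analysis:

1. screens candidate factors univariately (chi-square / Fisher / t-test;
   retain p <= 0.1 with at least 5 exposed cases),
2. fits one Cox proportional-hazards model per retained factor, with SUID as
   the event, non-SUID deaths censored at the day of death and survivors at
   day 365, each model adjusted for the maternal covariate set plus maternal
   nicotine use (except the nicotine model itself), and
3. re-runs the per-factor models after excluding SUID cases by genetic-risk
   tier (without very strong; without strong or very strong) and, as
   sensitivity analyses, by etiology category (without probable; without
   probable or possible). Survivors are never excluded, so attenuation of a
   factor across comparisons reflects the removed cases only.

Cox fits are delegated to :class:`lifelines.CoxPHFitter` (Efron tie
handling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

__all__ = [
    "OUTCOMES",
    "EffectEstimate",
    "AnalysisSpec",
    "DEFAULT_ADJUSTMENT",
    "DEFAULT_COMPARISONS",
    "NonEstimableError",
    "compute_rates",
    "univariate_screen",
    "impute_covariates",
    "fit_adjusted_cox",
    "stratified_reanalysis",
    "effects_to_frame",
]

OUTCOMES = ("suid", "other_death", "alive")

#: Maternal covariates every per-factor model adjusts for. Nicotine is added
#: separately (except in the nicotine model itself).
DEFAULT_ADJUSTMENT = (
    "race_ethnicity",
    "mat_age_band",
    "education_lt12",
    "bmi_overweight",
    "prenatal_care_inadequate",
    "payer",
)

SMOKING_FACTOR = "nicotine"


class NonEstimableError(RuntimeError):
    """The factor effect cannot be estimated (no events in a stratum)."""


@dataclass(frozen=True)
class EffectEstimate:
    """Adjusted hazard ratio for one factor level."""

    factor: str
    level: str
    ahr: float
    ci_low: float
    ci_high: float
    p_value: float
    n_events: int

    @property
    def significant(self) -> bool:
        return bool(self.p_value < 0.05)


@dataclass(frozen=True)
class AnalysisSpec:
    """One comparison: which SUID cases to exclude and how to adjust."""

    label: str
    exclude_tiers: frozenset[str] = frozenset()
    exclude_categories: frozenset[str] = frozenset()
    adjustment: tuple[str, ...] = DEFAULT_ADJUSTMENT
    alpha: float = 0.1
    min_count: int = 5


#: The three primary comparisons and the two sensitivity comparisons.
DEFAULT_COMPARISONS = (
    AnalysisSpec(label="all_suid"),
    AnalysisSpec(
        label="without_very_strong", exclude_tiers=frozenset({"very_strong"})
    ),
    AnalysisSpec(
        label="without_strong_or_very_strong",
        exclude_tiers=frozenset({"strong", "very_strong"}),
    ),
    AnalysisSpec(
        label="without_probable", exclude_categories=frozenset({"probable"})
    ),
    AnalysisSpec(
        label="without_probable_or_possible",
        exclude_categories=frozenset({"probable", "possible"}),
    ),
)


def compute_rates(numerator: int, denominator: int, per: float = 100_000) -> float:
    """Scaled rate, rounded as reported: one decimal, integers at >= 100."""
    if denominator <= 0:
        raise ValueError(f"denominator must be > 0, got {denominator}")
    if not (0 <= numerator <= denominator):
        raise ValueError(
            f"numerator must be in [0, denominator], got {numerator}"
        )
    value = numerator / denominator * per
    return float(round(value)) if value >= 100 else round(value, 1)


# -------------------------------------------------------------- univariate

def _is_continuous(col: pd.Series) -> bool:
    return pd.api.types.is_float_dtype(col) and col.nunique() > 10


def univariate_screen(
    cohort: pd.DataFrame,
    factors: Sequence[str],
    alpha: float = 0.1,
    min_count: int = 5,
) -> pd.DataFrame:
    """Screen factors for inclusion in multivariable models.

    SUID cases are compared against infants alive at one year. Categorical
    factors use chi-square when expected counts allow, Fisher's exact test
    for sparse 2x2 tables; continuous factors use Welch's t-test. A factor is
    retained when p <= ``alpha`` and at least ``min_count`` SUID cases carry
    a non-reference level.
    """
    sub = cohort[cohort["outcome"].isin(["suid", "alive"])]
    is_case = (sub["outcome"] == "suid").to_numpy()
    rows = []
    for factor in factors:
        col = sub[factor]
        if col.dropna().nunique() < 2:
            warnings.warn(f"{factor}: single level, skipped", stacklevel=2)
            continue
        if _is_continuous(col):
            a = col[is_case].dropna()
            b = col[~is_case].dropna()
            p = stats.ttest_ind(a, b, equal_var=False).pvalue
            test = "t"
            n_exposed_cases = int(is_case.sum())
        else:
            table = pd.crosstab(col, is_case)
            if True not in table.columns:
                continue
            expected = stats.contingency.expected_freq(table.to_numpy())
            if table.shape == (2, 2) and (expected < 5).any():
                p = stats.fisher_exact(table.to_numpy()).pvalue
                test = "fisher"
            else:
                p = stats.chi2_contingency(table.to_numpy()).pvalue
                test = "chi2"
            ref = col.value_counts().idxmax()
            n_exposed_cases = int(((col != ref) & is_case).sum())
        rows.append(
            {
                "factor": factor,
                "test": test,
                "p_value": float(p),
                "n_exposed_cases": n_exposed_cases,
                "retained": bool(p <= alpha and n_exposed_cases >= min_count),
            }
        )
    return pd.DataFrame(rows)


# -------------------------------------------------------------- imputation

def impute_covariates(
    cohort: pd.DataFrame,
    seed: int,
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Single imputation of missing covariates by seeded marginal draw.

    Each missing value is replaced by a draw from the observed distribution
    of its column; a ``<col>_imputed`` flag column records which values were
    filled. Outcome and event time must be complete.
    """
    if cohort["outcome"].isna().any() or cohort["event_time"].isna().any():
        raise ValueError("outcome/event_time must not contain missing values")
    out = cohort.copy()
    targets = [
        c
        for c in (columns or cohort.columns)
        if c not in ("infant_id", "outcome", "event_time")
        and out[c].isna().any()
    ]
    for col in sorted(targets):
        observed = out[col].dropna()
        if observed.empty:
            raise ValueError(f"{col}: entirely missing, cannot impute")
        mask = out[col].isna()
        rng = np.random.default_rng([seed, _name_key(col)])
        draws = observed.sample(
            n=int(mask.sum()),
            replace=True,
            random_state=np.random.RandomState(rng.integers(2**31)),
        ).to_numpy()
        out.loc[mask, col] = draws
        out[f"{col}_imputed"] = mask.to_numpy()
    return out


def _name_key(name: str) -> int:
    """Stable per-name stream key (hash() is salted across processes)."""
    import zlib

    return zlib.crc32(name.encode()) % (2**31)


# --------------------------------------------------------------- Cox models

def _dummies(col: pd.Series, name: str, ref: str | None = None) -> pd.DataFrame:
    """Indicator columns against a reference level (default: most frequent)."""
    ref = ref if ref is not None else col.value_counts().idxmax()
    levels = [lv for lv in sorted(col.dropna().unique().astype(str)) if lv != str(ref)]
    out = pd.DataFrame(index=col.index)
    as_str = col.astype(str)
    for lv in levels:
        out[f"{name}[{lv}]"] = (as_str == lv).astype(float)
    return out


def _design_column(cohort: pd.DataFrame, name: str) -> pd.DataFrame:
    col = cohort[name]
    if pd.api.types.is_numeric_dtype(col) and col.dropna().isin([0, 1]).all():
        return col.astype(float).to_frame(name)
    if _is_continuous(col):
        return col.astype(float).to_frame(name)
    return _dummies(col, name)


def fit_adjusted_cox(
    cohort: pd.DataFrame,
    factor: str,
    spec: AnalysisSpec | None = None,
    robust: bool = False,
) -> list[EffectEstimate]:
    """Adjusted Cox proportional-hazards model for one factor.

    Event is SUID; non-SUID deaths are censored at the day of death and
    survivors at day 365. The model adjusts for ``spec.adjustment`` (those
    columns present in the cohort) plus maternal nicotine use, except when
    the factor itself is nicotine. Returns one estimate per non-reference
    level (a single estimate for a binary factor).
    """
    spec = spec or AnalysisSpec(label="all_suid")
    event = (cohort["outcome"] == "suid").astype(int)
    n_events = int(event.sum())
    if n_events == 0:
        raise NonEstimableError("no SUID events in cohort")

    design = [_design_column(cohort, factor)]
    adjusters = [c for c in spec.adjustment if c in cohort.columns and c != factor]
    if (
        factor != SMOKING_FACTOR
        and SMOKING_FACTOR in cohort.columns
        and SMOKING_FACTOR not in adjusters
    ):
        adjusters.append(SMOKING_FACTOR)
    for name in adjusters:
        design.append(_design_column(cohort, name))
    X = pd.concat(design, axis=1)

    factor_cols = list(design[0].columns)
    for c in factor_cols:
        strata = X[c] > 0
        if event[strata].sum() == 0 or event[~strata].sum() == 0:
            raise NonEstimableError(
                f"{factor} level {c!r}: no SUID events in one stratum"
            )

    df = X.copy()
    df["duration"] = cohort["event_time"].astype(float)
    df["event"] = event.to_numpy()
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="duration", event_col="event", robust=robust)
    except ConvergenceError as exc:  # degenerate design
        raise NonEstimableError(f"{factor}: Cox fit did not converge") from exc

    out = []
    summary = cph.summary
    for c in factor_cols:
        level = c[len(factor) + 1 : -1] if c.startswith(f"{factor}[") else c
        row = summary.loc[c]
        out.append(
            EffectEstimate(
                factor=factor,
                level=level,
                ahr=float(row["exp(coef)"]),
                ci_low=float(row["exp(coef) lower 95%"]),
                ci_high=float(row["exp(coef) upper 95%"]),
                p_value=float(row["p"]),
                n_events=n_events,
            )
        )
    return out


def _excluded_case_ids(
    case_risk_table: pd.DataFrame, spec: AnalysisSpec
) -> set[str]:
    mask = case_risk_table["tier"].isin(spec.exclude_tiers) | case_risk_table[
        "case_category"
    ].isin(spec.exclude_categories)
    return set(case_risk_table.loc[mask, "case_id"])


def stratified_reanalysis(
    cohort: pd.DataFrame,
    case_risk_table: pd.DataFrame,
    factors: Sequence[str],
    specs: Sequence[AnalysisSpec] = DEFAULT_COMPARISONS,
    robust: bool = False,
) -> dict[str, pd.DataFrame]:
    """Re-fit every factor model under each comparison's case exclusions.

    ``case_risk_table`` must carry ``case_id``, ``tier`` and
    ``case_category`` for every SUID case in the cohort; excluded SUID cases
    are dropped entirely, while the survivor pool is identical across
    comparisons. Returns one estimates table per comparison label.
    """
    suid_ids = set(cohort.loc[cohort["outcome"] == "suid", "infant_id"])
    known = set(case_risk_table["case_id"])
    orphans = sorted(suid_ids - known)
    if orphans:
        raise ValueError(
            f"SUID cases missing from case risk table: {orphans[:10]}"
            + ("..." if len(orphans) > 10 else "")
        )

    tables: dict[str, pd.DataFrame] = {}
    for spec in specs:
        drop = _excluded_case_ids(case_risk_table, spec) & suid_ids
        sub = cohort[~cohort["infant_id"].isin(drop)]
        estimates: list[EffectEstimate] = []
        for factor in factors:
            try:
                estimates.extend(fit_adjusted_cox(sub, factor, spec, robust))
            except NonEstimableError:
                estimates.append(
                    EffectEstimate(
                        factor=factor,
                        level="NA",
                        ahr=float("nan"),
                        ci_low=float("nan"),
                        ci_high=float("nan"),
                        p_value=float("nan"),
                        n_events=0,
                    )
                )
        tables[spec.label] = effects_to_frame(estimates)
    return tables


def effects_to_frame(estimates: Sequence[EffectEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "factor": e.factor,
                "level": e.level,
                "ahr": e.ahr,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "p": e.p_value,
                "n_events": e.n_events,
                "significant": e.significant,
            }
            for e in estimates
        ]
    )
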