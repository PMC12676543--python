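"""Rates, univariate screening, imputation, and adjusted Cox models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from suidgxe import (
    AnalysisSpec,
    EFactorSpec,
    SimulationConfig,
    compute_rates,
    fit_adjusted_cox,
    impute_covariates,
    simulate_cohort,
    stratified_reanalysis,
    univariate_screen,
)
from suidgxe.survival import DEFAULT_COMPARISONS, NonEstimableError


class TestComputeRates:
    @pytest.mark.parametrize(
        "num,den,per,expected",
        [
            (227, 620_606, 100_000, 36.6),
            (2_686, 620_606, 100_000, 433.0),
            (0, 1_000, 100_000, 0.0),
        ],
    )
    def test_reported_rates(self, num, den, per, expected):
        assert compute_rates(num, den, per) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_rates(1, 0)
        with pytest.raises(ValueError):
            compute_rates(5, 4)


def _screen_cohort(n=6000, seed=0, rr=1.0, prevalence=0.05, n_cases=250):
    """Cohort where exposure multiplies the odds of being a SUID case."""
    rng = np.random.default_rng(seed)
    is_case = np.zeros(n, dtype=bool)
    is_case[:n_cases] = True
    p = np.where(is_case, min(prevalence * rr, 0.95), prevalence)
    exposed = rng.random(n) < p
    return pd.DataFrame(
        {
            "infant_id": [f"I{i}" for i in range(n)],
            "outcome": np.where(is_case, "suid", "alive"),
            "event_time": np.where(is_case, 100, 365),
            "exposure": exposed.astype(int),
        }
    )


class TestUnivariateScreen:
    def test_null_factor_excluded_most_seeds(self):
        hits = 0
        for seed in range(10):
            cohort = _screen_cohort(seed=seed, rr=1.0)
            row = univariate_screen(cohort, ["exposure"]).iloc[0]
            hits += row["retained"]
        # p uniform under the null: ~1 retention expected at alpha 0.1
        assert hits <= 4

    def test_planted_association_included(self):
        hits = 0
        for seed in range(10):
            cohort = _screen_cohort(seed=seed, rr=3.0)
            row = univariate_screen(cohort, ["exposure"]).iloc[0]
            hits += row["retained"]
        assert hits >= 9

    def test_count_gate_excludes_sparse_factor(self):
        cohort = _screen_cohort(seed=1, rr=1.0, prevalence=0.001)
        # plant a perfect but sparse association: 4 exposed cases only
        cohort["exposure"] = 0
        cohort.loc[cohort.index[:4], "exposure"] = 1  # first rows are cases
        row = univariate_screen(cohort, ["exposure"]).iloc[0]
        assert row["n_exposed_cases"] == 4
        assert not row["retained"]

    def test_degenerate_factor_skipped_with_warning(self):
        cohort = _screen_cohort(seed=0)
        cohort["constant"] = 1
        with pytest.warns(UserWarning, match="constant"):
            out = univariate_screen(cohort, ["constant", "exposure"])
        assert list(out["factor"]) == ["exposure"]

    def test_continuous_factor_uses_t_test(self):
        cohort = _screen_cohort(seed=0)
        rng = np.random.default_rng(0)
        cohort["age"] = rng.normal(30, 5, len(cohort))
        out = univariate_screen(cohort, ["age"])
        assert out.iloc[0]["test"] == "t"


class TestImputeCovariates:
    def _cohort_with_missing(self, frac=0.1, n=5000, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "infant_id": [f"I{i}" for i in range(n)],
                "outcome": "alive",
                "event_time": 365,
                "payer": rng.choice(["private", "public", "other"],
                                    n, p=[0.5, 0.4, 0.1]),
            }
        )
        mask = rng.random(n) < frac
        df.loc[mask, "payer"] = np.nan
        return df

    def test_no_missingness_is_identity(self):
        df = self._cohort_with_missing(frac=0.0)
        out = impute_covariates(df, seed=1)
        pd.testing.assert_frame_equal(out, df)

    def test_deterministic_given_seed(self):
        df = self._cohort_with_missing()
        a = impute_covariates(df, seed=7)
        b = impute_covariates(df, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_imputed_marginal_matches_observed(self):
        df = self._cohort_with_missing(frac=0.1, n=20_000)
        out = impute_covariates(df, seed=3)
        assert not out["payer"].isna().any()
        filled = out.loc[out["payer_imputed"], "payer"].value_counts()
        observed = df["payer"].dropna().value_counts(normalize=True)
        expected = observed.reindex(filled.index) * filled.sum()
        chi2 = ((filled - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=len(filled) - 1) > 0.001

    def test_fully_missing_column_rejected(self):
        df = self._cohort_with_missing()
        df["ghost"] = np.nan
        with pytest.raises(ValueError, match="ghost"):
            impute_covariates(df, seed=0)


def _ph_cohort(seed, hr=2.0, prevalence=0.10, n=60_000, incidence=0.003):
    cfg = SimulationConfig(
        n_births=n,
        seed=seed,
        e_factors=(EFactorSpec("exposure", prevalence, hr),),
        suid_incidence=incidence,
        competing_incidence=0.001,
    )
    return simulate_cohort(cfg)[0]


class TestFitAdjustedCox:
    def test_recovers_planted_hazard_ratio(self):
        cohort = _ph_cohort(seed=11)
        est = fit_adjusted_cox(cohort, "exposure")[0]
        assert est.ci_low < 2.0 < est.ci_high
        assert est.ahr == pytest.approx(2.0, rel=0.35)

    def test_null_factor_ci_covers_one(self):
        covered = 0
        for seed in range(5):
            cohort = _ph_cohort(seed=seed, hr=1.0, n=30_000)
            est = fit_adjusted_cox(cohort, "exposure")[0]
            covered += est.ci_low < 1.0 < est.ci_high
        assert covered >= 4

    def test_all_exposed_not_estimable(self):
        cohort = _ph_cohort(seed=2, n=5_000)
        cohort["exposure"] = 1
        with pytest.raises(NonEstimableError):
            fit_adjusted_cox(cohort, "exposure")

    def test_categorical_factor_levels_against_reference(self):
        cohort = _ph_cohort(seed=3, n=30_000)
        ests = fit_adjusted_cox(cohort, "payer")
        levels = {e.level for e in ests}
        # 'private' is the modal reference level
        assert levels == {"public", "other"}

    def test_censoring_conservation(self):
        cohort = _ph_cohort(seed=4, n=20_000)
        n_event = (cohort["outcome"] == "suid").sum()
        n_death_censor = (cohort["outcome"] == "other_death").sum()
        n_alive = (cohort["outcome"] == "alive").sum()
        assert n_event + n_death_censor + n_alive == len(cohort)
        assert (cohort.loc[cohort["outcome"] == "alive", "event_time"] == 365).all()
        deaths = cohort["outcome"] != "alive"
        assert cohort.loc[deaths, "event_time"].between(1, 365).all()


@pytest.fixture(scope="module")
def cohort_and_risk():
    cohort = _ph_cohort(seed=21, n=40_000)
    suid_ids = cohort.loc[cohort["outcome"] == "suid", "infant_id"].tolist()
    rng = np.random.default_rng(0)
    tiers = rng.choice(["very_strong", "strong", "weak"], len(suid_ids),
                       p=[0.12, 0.34, 0.54])
    cats = np.where(tiers == "weak", "none", "probable")
    risk = pd.DataFrame(
        {"case_id": suid_ids, "tier": tiers, "case_category": cats}
    )
    return cohort, risk


class TestStratifiedReanalysis:
    def test_comparison_case_counts(self, cohort_and_risk):
        cohort, risk = cohort_and_risk
        n_all = len(risk)
        n_vs = (risk["tier"] == "very_strong").sum()
        n_strong = (risk["tier"] == "strong").sum()
        tables = stratified_reanalysis(cohort, risk, ["exposure"],
                                       specs=DEFAULT_COMPARISONS[:3])
        assert tables["all_suid"].iloc[0]["n_events"] == n_all
        assert tables["without_very_strong"].iloc[0]["n_events"] == n_all - n_vs
        assert (
            tables["without_strong_or_very_strong"].iloc[0]["n_events"]
            == n_all - n_vs - n_strong
        )

    def test_survivor_pool_never_shrinks(self, cohort_and_risk):
        cohort, risk = cohort_and_risk
        # excluding all SUID cases by tier still leaves every survivor
        spec = AnalysisSpec(
            label="x", exclude_tiers=frozenset({"very_strong", "strong", "weak"})
        )
        drop = set(risk["case_id"])
        kept = cohort[~cohort["infant_id"].isin(drop)]
        assert (kept["outcome"] != "suid").all()
        assert (kept["outcome"] == "alive").sum() == (
            cohort["outcome"] == "alive"
        ).sum()

    def test_orphan_cases_rejected(self, cohort_and_risk):
        cohort, risk = cohort_and_risk
        with pytest.raises(ValueError, match="missing"):
            stratified_reanalysis(cohort, risk.iloc[:-2], ["exposure"],
                                  specs=DEFAULT_COMPARISONS[:1])

    def test_estimates_stable_without_gxe_structure(self, cohort_and_risk):
        # tiers independent of exposure: point estimates agree across
        # comparisons within Monte-Carlo error
        cohort, risk = cohort_and_risk
        tables = stratified_reanalysis(cohort, risk, ["exposure"],
                                       specs=DEFAULT_COMPARISONS[:3])
        ahrs = [t.iloc[0]["ahr"] for t in tables.values()]
        assert max(ahrs) / min(ahrs) < 1.8
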