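"""Synthetic cohorts, disorder catalogs and WGS findings with known truth.

The study's raw data are restricted, so every pipeline stage is exercised on
simulated data whose ground truth is known by construction:

* ``simulate_cohort`` draws one row per birth. Binary exposures are drawn at
  configured prevalences (optionally correlated within groups); SUID event
  times follow an exponential proportional-hazards model over days 1-365
  with per-factor hazard ratios; competing non-SUID deaths are drawn
  independently; the first event wins and survivors are censored at day 365.
  Defaults reproduce the study's scale in miniature: SUID incidence
  36.6/100,000 live births, all-cause infant mortality 433/100,000, and
  exposure prevalences/hazards mirroring the significant cohort factors.

* ``simulate_disorder_catalog`` emits disorders whose infant-death
  likelihoods land prevalence risk ratios in chosen tier bands, with
  intervention availability flagged at a configured rate (default 83%).

* ``simulate_findings`` plants per-case etiology categories (probable /
  possible / none at the study shares 16% / 47%) and risk tiers (very
  strong / strong / weak near 12% / 34% / 54%), drawing variant classes and
  genotype frequencies strictly inside the classification bands so the
  classifier and PRR engine recover the planted truth exactly. Locus
  assignment is skewed toward uniqueness (extreme locus heterogeneity) and a
  configurable share of cases receives more than one finding (G x G risk).

All randomness flows from the single config seed, with an independent
stream per component so adding a factor never perturbs the others.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import DisorderProfile

__all__ = [
    "EFactorSpec",
    "GxESpec",
    "GRiskSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_disorder_catalog",
    "simulate_findings",
    "gxe_case_risk_table",
]

DAYS = 365


@dataclass(frozen=True)
class EFactorSpec:
    """One binary exposure: prevalence, true hazard ratio, correlation group."""

    name: str
    prevalence: float
    hr: float = 1.0
    group: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.prevalence < 1):
            raise ValueError(f"{self.name}: prevalence must be in (0, 1)")
        if self.hr <= 0:
            raise ValueError(f"{self.name}: hr must be > 0")


#: Significant cohort factors with their reported adjusted hazard ratios,
#: used as the generator's true effects.
DEFAULT_E_FACTORS = (
    EFactorSpec("nicotine", 0.02, 2.9),
    EFactorSpec("cannabis", 0.01, 3.7, group="substance"),
    EFactorSpec("other_substance", 0.015, 2.6, group="substance"),
    EFactorSpec("depression", 0.03, 2.1),
    EFactorSpec("multiparous", 0.60, 1.5),
    EFactorSpec("preterm", 0.08, 2.1, group="birth"),
    EFactorSpec("very_preterm", 0.015, 3.4, group="birth"),
    EFactorSpec("rds", 0.01, 2.5, group="birth"),
    EFactorSpec("preexisting_htn", 0.02, 2.4),
    EFactorSpec("malformation", 0.02, 1.5),
)

#: Maternal adjustment covariates: level -> probability. Null effects; they
#: exist so adjusted models have realistic design matrices.
DEFAULT_ADJUSTERS: dict[str, dict[str, float]] = {
    "race_ethnicity": {
        "white": 0.42,
        "hispanic": 0.34,
        "black": 0.05,
        "asian": 0.12,
        "other": 0.07,
    },
    "mat_age_band": {"lt18": 0.02, "18_34": 0.75, "35plus": 0.23},
    "payer": {"private": 0.50, "public": 0.45, "other": 0.05},
}

DEFAULT_BINARY_ADJUSTERS: dict[str, float] = {
    "education_lt12": 0.12,
    "bmi_overweight": 0.50,
    "prenatal_care_inadequate": 0.08,
}


@dataclass(frozen=True)
class GxESpec:
    """Planted gene-environment confounding scenario.

    A small carrier subset has strongly elevated SUID hazard; one exposure
    (``confounded_factor``) is much more common among carriers but has no
    direct effect on hazard. Its marginal association with SUID is therefore
    entirely explained by genetic risk and should vanish when carrier SUID
    cases are excluded, while a directly causal factor should not attenuate.
    """

    carrier_prevalence: float = 0.005
    carrier_hr: float = 30.0
    confounded_factor: str = "g_linked_rds"
    exposure_rate_carriers: float = 0.5
    exposure_rate_noncarriers: float = 0.02
    carrier_tier: str = "strong"


@dataclass(frozen=True)
class GRiskSpec:
    """Planted genetic-risk structure for SUID cases.

    Category fractions are the study shares of probable/possible etiologies;
    tier fractions are the very-strong/strong shares of cases. Very strong
    tiers are drawn among probable-etiology cases only (a single possible
    finding cannot exceed the very-strong floor after the square-root rule).
    """

    frac_probable: float = 0.16
    frac_possible: float = 0.47
    frac_very_strong: float = 0.12
    frac_strong: float = 0.34
    multi_finding_rate: float = 0.30  # share of genetic cases with >1 finding
    vus_upgrade_rate: float = 0.12  # probable calls that are phenotype-upgraded VUS
    lp_secondary_rate: float = 5 / 149  # possible calls that are relaxed-band LP
    ar_rate: float = 0.14
    xl_rate: float = 0.03
    n_disorders_per_band: int = 60
    intervention_rate: float = 0.83
    P: float = 101 / 100_000
    strong_floor: float = 3.7
    very_strong_floor: float = 99.0
    ceiling: float = 990.0
    f_primary: float = 8.2199633560726e-06  # larger of the two cutoffs
    f_secondary: float = 3.6e-5


@dataclass(frozen=True)
class SimulationConfig:
    n_births: int = 100_000
    seed: int = 0
    e_factors: tuple[EFactorSpec, ...] = DEFAULT_E_FACTORS
    #: cumulative one-year SUID probability at baseline covariates
    suid_incidence: float = 36.6e-5
    #: cumulative one-year competing (non-SUID) death probability
    competing_incidence: float = (2686 - 227) / 620_606
    gxe: GxESpec | None = None
    g_risk: GRiskSpec = field(default_factory=GRiskSpec)

    def __post_init__(self) -> None:
        if self.n_births < 1:
            raise ValueError("n_births must be >= 1")
        if not (0 < self.suid_incidence < 1):
            raise ValueError("suid_incidence must be in (0, 1)")
        if not (0 <= self.competing_incidence < 1):
            raise ValueError("competing_incidence must be in [0, 1)")


@dataclass
class GroundTruth:
    """What the generator actually did, for round-trip checks."""

    factor_table: pd.DataFrame  # name, prevalence, true_hr
    linear_predictor: np.ndarray  # per-infant log hazard ratio
    carrier: np.ndarray | None = None  # GxE carrier flags, if simulated
    case_truth: pd.DataFrame | None = None  # planted per-case category/tier


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent, deterministic stream keyed by (seed, component name)."""
    return np.random.default_rng([seed, zlib.crc32(name.encode()) % (2**31)])


# ------------------------------------------------------------------ cohort

def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a synthetic birth cohort with proportional-hazards SUID outcome."""
    n = config.n_births
    cohort = pd.DataFrame(
        {"infant_id": [f"I{i:07d}" for i in range(n)]}
    )

    # maternal adjustment covariates (null effects)
    for name, levels in DEFAULT_ADJUSTERS.items():
        rng = _stream(config.seed, f"adj:{name}")
        labels = list(levels)
        probs = np.array([levels[k] for k in labels])
        cohort[name] = rng.choice(labels, size=n, p=probs / probs.sum())
    for name, prev in DEFAULT_BINARY_ADJUSTERS.items():
        rng = _stream(config.seed, f"adj:{name}")
        cohort[name] = (rng.random(n) < prev).astype(int)

    # exposures: factors sharing a correlation group share one latent uniform
    log_hr = np.zeros(n)
    group_u: dict[str, np.ndarray] = {}
    truth_rows = []
    for spec in config.e_factors:
        if spec.group is not None:
            if spec.group not in group_u:
                group_u[spec.group] = _stream(
                    config.seed, f"group:{spec.group}"
                ).random(n)
            u = group_u[spec.group]
        else:
            u = _stream(config.seed, f"factor:{spec.name}").random(n)
        exposed = u < spec.prevalence
        cohort[spec.name] = exposed.astype(int)
        log_hr += exposed * math.log(spec.hr)
        truth_rows.append(
            {"name": spec.name, "prevalence": spec.prevalence, "true_hr": spec.hr}
        )

    carrier = None
    if config.gxe is not None:
        gxe = config.gxe
        rng = _stream(config.seed, "gxe:carrier")
        carrier = rng.random(n) < gxe.carrier_prevalence
        log_hr += carrier * math.log(gxe.carrier_hr)
        rng2 = _stream(config.seed, "gxe:exposure")
        rate = np.where(
            carrier, gxe.exposure_rate_carriers, gxe.exposure_rate_noncarriers
        )
        cohort[gxe.confounded_factor] = (rng2.random(n) < rate).astype(int)
        truth_rows.append(
            {
                "name": gxe.confounded_factor,
                "prevalence": float(rate.mean()),
                "true_hr": 1.0,
            }
        )

    # exponential event times over one year of life
    base_rate = -math.log1p(-config.suid_incidence) / DAYS  # per day
    rates = base_rate * np.exp(log_hr)
    rng_t = _stream(config.seed, "time:suid")
    t_suid = rng_t.exponential(1.0, size=n) / rates
    if config.competing_incidence > 0:
        comp_rate = -math.log1p(-config.competing_incidence) / DAYS
        t_comp = _stream(config.seed, "time:competing").exponential(
            1.0 / comp_rate, size=n
        )
    else:
        t_comp = np.full(n, np.inf)

    suid_event = (t_suid <= t_comp) & (t_suid < DAYS)
    comp_event = (t_comp < t_suid) & (t_comp < DAYS)
    event_time = np.full(n, DAYS, dtype=int)
    event_time[suid_event] = np.clip(np.ceil(t_suid[suid_event]), 1, DAYS)
    event_time[comp_event] = np.clip(np.ceil(t_comp[comp_event]), 1, DAYS)
    outcome = np.where(suid_event, "suid", np.where(comp_event, "other_death", "alive"))

    death_frac = (outcome != "alive").mean()
    if death_frac > 0.5:
        raise ValueError(
            f"configured hazards kill {death_frac:.0%} of the cohort; "
            "check incidence parameters"
        )

    cohort["outcome"] = outcome
    cohort["event_time"] = event_time

    truth = GroundTruth(
        factor_table=pd.DataFrame(truth_rows),
        linear_predictor=log_hr,
        carrier=carrier,
    )
    return cohort, truth


# ----------------------------------------------------------------- catalog

#: p_death sampling ranges per band. Band boundaries keep a margin inside the
#: tier floors so products with small co-findings cannot cross a boundary.
_BANDS = {
    # probable PRR > 110 (very strong with margin)
    "high": (0.12, 0.80),
    # probable PRR in [4.5, 40]: strong even with two 1.4x co-findings
    "mid": (0.0046, 0.040),
    # probable PRR <= 1.6: weak even with two 1.4x co-findings
    "low": (0.0003, 0.0016),
    # possible PRR (sqrt) in [4.4, 9.0]: strong
    "mid_possible": (0.020, 0.082),
    # possible PRR (sqrt) in [1.0, 1.4]: near-unit co-finding multiplier
    "near_one": (0.00101, 0.00198),
}

_ORGANS = (
    ("congenital-anomaly", 0.39),
    ("cardiac", 0.12),
    ("seizure", 0.09),
    ("immune", 0.08),
    ("respiratory", 0.10),
    ("other", 0.22),
)


def simulate_disorder_catalog(
    config: SimulationConfig,
) -> dict[str, DisorderProfile]:
    """Catalog of synthetic disorders with tier-banded death likelihoods."""
    g = config.g_risk
    rng = _stream(config.seed, "catalog")
    organs, organ_p = zip(*_ORGANS)
    organ_p = np.array(organ_p) / sum(organ_p)
    catalog: dict[str, DisorderProfile] = {}
    idx = 0
    for band, (lo, hi) in _BANDS.items():
        for _ in range(g.n_disorders_per_band):
            idx += 1
            did = f"D{idx:04d}"
            p_death = float(rng.uniform(lo, hi))
            catalog[did] = DisorderProfile(
                disorder_id=did,
                name=f"synthetic disorder {idx} ({band})",
                birth_prevalence=float(10 ** rng.uniform(-6, -4)),
                p_death=p_death,
                infant_death_associated=True,
                intervention_available=bool(rng.random() < g.intervention_rate),
                principal_organ=str(rng.choice(organs, p=organ_p)),
            )
    return catalog


def _band_of(profile: DisorderProfile) -> str:
    return profile.name.rsplit("(", 1)[1].rstrip(")")


class _BandPool:
    """Draws disorders from a band, mostly without replacement.

    The pool is a shuffled queue per band; refills (reshuffled) once
    exhausted, which is what produces the few recurrent loci.
    """

    def __init__(self, catalog: Mapping[str, DisorderProfile], rng):
        self.rng = rng
        self.by_band: dict[str, list[str]] = {}
        for did, prof in catalog.items():
            self.by_band.setdefault(_band_of(prof), []).append(did)
        for ids in self.by_band.values():
            ids.sort()
        self.queues: dict[str, list[str]] = {}

    def draw(self, band: str, exclude: set[str]) -> str:
        for _ in range(200):
            q = self.queues.get(band)
            if not q:
                q = list(self.by_band[band])
                self.rng.shuffle(q)
                self.queues[band] = q
            did = q.pop()
            if did not in exclude:
                return did
        raise RuntimeError(f"cannot draw a fresh disorder from band {band}")


def _draw_f_obs(rng, lo: float, hi: float) -> float:
    """Log-uniform frequency strictly inside (lo, hi)."""
    return float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))


def simulate_findings(
    case_ids: Sequence[str],
    catalog: Mapping[str, DisorderProfile],
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant WGS findings for SUID cases with known categories and tiers.

    Returns the findings table (classifier input schema) and the planted
    per-case truth (``case_id, category, tier, combined_prr``). Frequencies
    are drawn strictly inside the classification bands, so the classifier
    and PRR engine recover the planted truth exactly.
    """
    g = config.g_risk
    rng = _stream(config.seed, "findings")
    pool = _BandPool(catalog, rng)

    if g.frac_very_strong > g.frac_probable + 1e-9:
        raise ValueError("frac_very_strong cannot exceed frac_probable")
    p_vs_given_prob = g.frac_very_strong / g.frac_probable if g.frac_probable else 0.0
    strong_from_probable = g.frac_probable - g.frac_very_strong
    if g.frac_strong < strong_from_probable - 1e-9:
        raise ValueError("frac_strong too small for the category fractions")
    p_strong_given_poss = (
        (g.frac_strong - strong_from_probable) / g.frac_possible
        if g.frac_possible
        else 0.0
    )
    if p_strong_given_poss > 1:
        raise ValueError("frac_strong too large for frac_possible")

    finding_rows = []
    truth_rows = []
    for cid in case_ids:
        u = rng.random()
        if u < g.frac_probable:
            category = "probable"
            tier = "very_strong" if rng.random() < p_vs_given_prob else "strong"
        elif u < g.frac_probable + g.frac_possible:
            category = "possible"
            tier = "strong" if rng.random() < p_strong_given_poss else "weak"
        else:
            category, tier = "none", "weak"

        if category == "none":
            truth_rows.append(
                {"case_id": cid, "category": "none", "tier": "weak",
                 "combined_prr": 1.0}
            )
            continue

        if category == "probable":
            band = {"very_strong": "high", "strong": "mid"}.get(tier, "low")
        else:
            band = "mid_possible" if tier == "strong" else "low"

        n_extra = 0
        if rng.random() < g.multi_finding_rate:
            n_extra = 1 + int(rng.random() < 0.3)
            if tier == "very_strong":
                n_extra += int(rng.random() < 0.5)

        used: set[str] = set()
        prrs: list[float] = []

        primary_id = pool.draw(band, used)
        used.add(primary_id)
        profile = catalog[primary_id]
        if category == "probable":
            prr = profile.p_death / g.P
            if rng.random() < g.vus_upgrade_rate:
                vclass, match = "VUS", True
            else:
                vclass = "P" if rng.random() < 0.6 else "LP"
                match = False
            f_obs = _draw_f_obs(rng, 1e-9, 0.8 * g.f_primary)
        else:
            prr = math.sqrt(profile.p_death / g.P)
            match = False
            if rng.random() < g.lp_secondary_rate:
                vclass = "LP"
                f_obs = _draw_f_obs(rng, 1.05 * g.f_primary, 0.95 * g.f_secondary)
            else:
                vclass = "VUS"
                f_obs = _draw_f_obs(rng, 1e-9, 0.8 * g.f_primary)
        prrs.append(prr)
        finding_rows.append(
            _finding_row(cid, profile, vclass, match, f_obs, rng, g)
        )

        for _ in range(n_extra):
            did = pool.draw("near_one", used)
            used.add(did)
            prof = catalog[did]
            prrs.append(math.sqrt(prof.p_death / g.P))
            finding_rows.append(
                _finding_row(
                    cid,
                    prof,
                    "VUS",
                    False,
                    _draw_f_obs(rng, 1e-9, 0.8 * g.f_primary),
                    rng,
                    g,
                )
            )

        combined = min(float(np.prod(prrs)), g.ceiling)
        if combined > g.very_strong_floor:
            got = "very_strong"
        elif combined >= g.strong_floor:
            got = "strong"
        else:
            got = "weak"
        if got != tier:  # band margins make this unreachable
            raise RuntimeError(
                f"{cid}: planted tier {tier} but PRR {combined:.2f} tiers {got}"
            )
        truth_rows.append(
            {"case_id": cid, "category": category, "tier": tier,
             "combined_prr": combined}
        )

    findings = pd.DataFrame(
        finding_rows,
        columns=[
            "case_id", "gene", "disorder_id", "variant_class", "moi",
            "moi_satisfied", "f_obs", "phenotype_match", "variant_type",
        ],
    )
    truth = pd.DataFrame(
        truth_rows, columns=["case_id", "category", "tier", "combined_prr"]
    )
    return findings, truth


def _finding_row(
    cid: str,
    profile: DisorderProfile,
    vclass: str,
    match: bool,
    f_obs: float,
    rng,
    g: GRiskSpec,
) -> dict:
    u = rng.random()
    moi = "AR" if u < g.ar_rate else ("XL" if u < g.ar_rate + g.xl_rate else "AD")
    return {
        "case_id": cid,
        "gene": f"GENE{profile.disorder_id[1:]}",
        "disorder_id": profile.disorder_id,
        "variant_class": vclass,
        "moi": moi,
        "moi_satisfied": True,
        "f_obs": f_obs,
        "phenotype_match": match,
        "variant_type": "structural" if rng.random() < 0.04 else "small",
    }


def gxe_case_risk_table(
    cohort: pd.DataFrame, truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Case risk table for the planted GxE scenario.

    Carrier SUID cases are tiered per the scenario (default strong, category
    probable); non-carrier SUID cases are weak with no genetic etiology.
    """
    if truth.carrier is None or config.gxe is None:
        raise ValueError("cohort was not simulated with a GxE scenario")
    is_suid = (cohort["outcome"] == "suid").to_numpy()
    carrier = np.asarray(truth.carrier)[is_suid]
    ids = cohort.loc[is_suid, "infant_id"].to_numpy()
    return pd.DataFrame(
        {
            "case_id": ids,
            "tier": np.where(carrier, config.gxe.carrier_tier, "weak"),
            "case_category": np.where(carrier, "probable", "none"),
        }
    )
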