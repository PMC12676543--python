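"""Etiology classification: QC rules, disorder selection, the call lattice."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from suidgxe import (
    GenotypeFinding,
    ThresholdParams,
    classification_summary,
    classify_case,
    classify_finding,
    qc_check,
    select_disorder,
)
from suidgxe.classify import NoEligibleDisorderError, UnknownDisorderError
from suidgxe.thresholds import primary_cutoff

PARAMS = ThresholdParams()
F_PRIMARY = primary_cutoff(PARAMS)

# frequency representatives: strictly below primary, between primary and
# secondary, above secondary
F_BELOW = 0.5 * F_PRIMARY
F_MID = 0.5 * (F_PRIMARY + PARAMS.f_secondary)
F_ABOVE = 2 * PARAMS.f_secondary


def make_finding(vclass="P", f_obs=F_BELOW, match=False, moi_ok=True):
    return GenotypeFinding(
        case_id="C1",
        gene="GENE1",
        disorder_id="D0001",
        variant_class=vclass,
        moi="AD",
        moi_satisfied=moi_ok,
        f_obs=f_obs,
        phenotype_match=match,
    )


class TestQcCheck:
    def test_all_passing(self, passing_qc_metrics):
        report = qc_check(passing_qc_metrics)
        assert report.overall_pass
        assert report.failed_metrics == []

    def test_titv_out_of_band_flagged(self, passing_qc_metrics):
        report = qc_check({**passing_qc_metrics, "titv_ratio": 2.3})
        assert not report.overall_pass
        assert report.failed_metrics == ["titv_ratio"]

    def test_duplicate_boundary_is_strict(self, passing_qc_metrics):
        report = qc_check({**passing_qc_metrics, "duplicate_fraction": 0.15})
        assert not report.overall_pass
        assert "duplicate_fraction" in report.failed_metrics

    def test_missing_metric_named(self, passing_qc_metrics):
        broken = dict(passing_qc_metrics)
        del broken["hom_het_ratio"]
        with pytest.raises(KeyError, match="hom_het_ratio"):
            qc_check(broken)


class TestSelectDisorder:
    def test_greatest_death_likelihood_wins(self, profile_factory):
        cardio = profile_factory("D0100", p_death=0.3, name="dilated cardiomyopathy")
        mild = profile_factory("D0200", p_death=0.01, name="tardive dystrophy")
        assert select_disorder("TTN", [mild, cardio]) is cardio

    def test_single_candidate(self, profile_factory):
        only = profile_factory("D0100")
        assert select_disorder("G", [only]) is only

    def test_tie_breaks_by_disorder_id_both_orders(self, profile_factory):
        a = profile_factory("D0100", p_death=0.2)
        b = profile_factory("D0200", p_death=0.2)
        assert select_disorder("G", [a, b]) is a
        assert select_disorder("G", [b, a]) is a

    def test_no_infant_death_candidate_signals(self, profile_factory):
        adult = profile_factory("D0100", infant_death_associated=False)
        with pytest.raises(NoEligibleDisorderError):
            select_disorder("G", [adult])


# Hand-written truth table for the full call lattice:
# (variant class, frequency band, phenotype match) -> call, given MOI ok and
# an infant-death-associated disorder. "below": f < primary cutoff;
# "mid": primary <= f < secondary; "above": f >= secondary.
TRUTH_TABLE = {
    ("P", "below", False): "probable",
    ("P", "below", True): "probable",
    ("P", "mid", False): "possible",
    ("P", "mid", True): "possible",
    ("P", "above", False): "excluded",
    ("P", "above", True): "excluded",
    ("LP", "below", False): "probable",
    ("LP", "below", True): "probable",
    ("LP", "mid", False): "possible",
    ("LP", "mid", True): "possible",
    ("LP", "above", False): "excluded",
    ("LP", "above", True): "excluded",
    ("VUS", "below", False): "possible",
    ("VUS", "below", True): "probable",  # phenotype upgrade
    ("VUS", "mid", False): "excluded",
    ("VUS", "mid", True): "excluded",
    ("VUS", "above", False): "excluded",
    ("VUS", "above", True): "excluded",
}
BAND_F = {"below": F_BELOW, "mid": F_MID, "above": F_ABOVE}


class TestClassifyFinding:
    @pytest.mark.parametrize(
        "vclass,band,match",
        list(itertools.product(["P", "LP", "VUS"], BAND_F, [False, True])),
    )
    def test_matches_truth_table(self, vclass, band, match, profile_factory):
        finding = make_finding(vclass, BAND_F[band], match)
        call = classify_finding(finding, profile_factory(), PARAMS)
        assert call == TRUTH_TABLE[(vclass, band, match)]

    @pytest.mark.parametrize("vclass,band,match",
                             list(itertools.product(["P", "LP", "VUS"], BAND_F,
                                                    [False, True])))
    def test_moi_unsatisfied_always_excluded(self, vclass, band, match,
                                             profile_factory):
        finding = make_finding(vclass, BAND_F[band], match, moi_ok=False)
        assert classify_finding(finding, profile_factory(), PARAMS) == "excluded"

    def test_non_infant_death_disorder_excluded(self, profile_factory):
        prof = profile_factory(infant_death_associated=False)
        assert classify_finding(make_finding(), prof, PARAMS) == "excluded"

    def test_phenotype_upgrade_never_demotes(self, profile_factory):
        rank = {"excluded": 0, "possible": 1, "probable": 2}
        for vclass, f in itertools.product(["P", "LP", "VUS"], BAND_F.values()):
            lo = classify_finding(make_finding(vclass, f, False),
                                  profile_factory(), PARAMS)
            hi = classify_finding(make_finding(vclass, f, True),
                                  profile_factory(), PARAMS)
            assert rank[hi] >= rank[lo]

    def test_cutoff_comparison_is_strict(self, profile_factory):
        at_cutoff = make_finding("P", F_PRIMARY)
        assert classify_finding(at_cutoff, profile_factory(), PARAMS) == "possible"
        at_secondary = make_finding("P", PARAMS.f_secondary)
        assert (
            classify_finding(at_secondary, profile_factory(), PARAMS) == "excluded"
        )


def _case_findings(calls, profile_factory, catalog):
    """Build findings engineered to receive the given calls."""
    spec = {
        "probable": ("P", F_BELOW, False),
        "possible": ("VUS", F_BELOW, False),
        "excluded": ("P", F_ABOVE, False),
    }
    findings = []
    for i, call in enumerate(calls):
        did = f"D{i:04d}"
        catalog[did] = profile_factory(did)
        vclass, f, match = spec[call]
        findings.append(
            GenotypeFinding(
                case_id="C1", gene=f"G{i}", disorder_id=did,
                variant_class=vclass, moi="AD", moi_satisfied=True,
                f_obs=f, phenotype_match=match,
            )
        )
    return findings


class TestClassifyCase:
    @pytest.mark.parametrize(
        "calls,expected_category,expected_retained",
        [
            (["probable"] + ["possible"] * 4, "probable", 5),
            ([], "none", 0),
            (["possible", "possible"], "possible", 2),
            (["excluded"], "none", 0),
            (["probable", "excluded"], "probable", 1),
        ],
    )
    def test_category_lattice(self, calls, expected_category, expected_retained,
                              profile_factory):
        catalog = {}
        findings = _case_findings(calls, profile_factory, catalog)
        cls = classify_case(findings, catalog, PARAMS)
        assert cls.case_category == expected_category
        assert len(cls.retained) == expected_retained

    def test_unknown_disorder_listed(self, profile_factory):
        finding = make_finding()
        with pytest.raises(UnknownDisorderError, match="D0001"):
            classify_case([finding], {}, PARAMS)

    @given(st.permutations(["probable", "possible", "possible", "excluded"]))
    @settings(max_examples=24, derandomize=True, deadline=None)
    def test_order_invariance(self, calls):
        catalog = {}
        from conftest import make_profile

        findings = _case_findings(list(calls), make_profile, catalog)
        cls = classify_case(findings, catalog, PARAMS)
        assert cls.case_category == "probable"
        assert sorted(c for _, c in cls.findings) == sorted(calls)


class TestClassificationSummary:
    def test_planted_counts_recovered(self, profile_factory):
        catalog = {}
        classifications = []
        plan = ["probable"] * 34 + ["possible"] * 99 + ["none"] * 79
        for i, cat in enumerate(plan):
            calls = {"probable": ["probable"], "possible": ["possible"],
                     "none": []}[cat]
            findings = _case_findings(calls, profile_factory, catalog)
            cls = classify_case(
                [f.__class__(**{**f.__dict__, "case_id": f"C{i}"}) for f in findings],
                catalog, PARAMS,
            )
            cls.case_id = f"C{i}"
            classifications.append(cls)
        summary = classification_summary(classifications)
        assert summary["n_cases"] == 212
        assert summary["n_probable"] == 34
        assert summary["pct_probable"] == 16
        assert summary["n_possible"] == 99
        assert summary["pct_possible"] == 47
        assert summary["n_genetic"] == 133

    def test_empty_input_all_zero(self):
        summary = classification_summary([])
        assert summary["n_cases"] == 0
        assert summary["pct_probable"] == 0
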