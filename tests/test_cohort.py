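import numpy as np
import pandas as pd
import pytest

from kampopreg import SimConfig, generate_bundle
from kampopreg.bundle import ClaimsBundle
from kampopreg.codelists import default_covariate_codelists
from kampopreg.cohort import (
    DataError,
    apply_eligibility,
    build_episodes_for_bundle,
    derive_covariates,
    link_mother_infant,
)


def _bundle_with(enrollment=None, links=None, diagnoses=None):
    empty_dx = pd.DataFrame(
        columns=["person_id", "icd10_code", "diagnosis_date", "ga_weeks", "ga_days"]
    )
    return ClaimsBundle(
        enrollment=enrollment if enrollment is not None else pd.DataFrame(
            columns=[
                "person_id", "family_id", "role", "coverage_start_month",
                "coverage_end_month", "birth_year_month", "sex",
            ]
        ),
        diagnoses=diagnoses if diagnoses is not None else empty_dx,
        prescriptions=pd.DataFrame(
            columns=[
                "person_id", "drug_code", "dispense_date", "admission_date",
                "claim_year_month", "days_of_supply", "as_needed",
            ]
        ),
        delivery_entries=pd.DataFrame(columns=["person_id", "entry_date", "entry_kind"]),
        links=links if links is not None else pd.DataFrame(
            columns=["mother_id", "infant_id", "family_id"]
        ),
    )


def _enrollment_row(pid, fam, role, start, end, birth=None, sex="F"):
    return dict(
        person_id=pid, family_id=fam, role=role, coverage_start_month=start,
        coverage_end_month=end, birth_year_month=birth, sex=sex,
    )


class TestLinkage:
    def test_infant_enrolled_in_birth_month_kept(self):
        enr = pd.DataFrame(
            [
                _enrollment_row("M1", "F1", "mother", "2014-01", "2017-01", "1985-05"),
                _enrollment_row("I1", "F1", "infant", "2015-03", "2016-06", "2015-03"),
            ]
        )
        links = pd.DataFrame([{"mother_id": "M1", "infant_id": "I1", "family_id": "F1"}])
        kept = link_mother_infant(_bundle_with(enr, links))
        assert list(kept["infant_id"]) == ["I1"]

    def test_infant_enrolled_two_months_late_dropped(self):
        enr = pd.DataFrame(
            [
                _enrollment_row("M1", "F1", "mother", "2014-01", "2017-01", "1985-05"),
                _enrollment_row("I1", "F1", "infant", "2015-05", "2016-06", "2015-03"),
            ]
        )
        links = pd.DataFrame([{"mother_id": "M1", "infant_id": "I1", "family_id": "F1"}])
        assert link_mother_infant(_bundle_with(enr, links)).empty

    def test_no_infants_gives_empty_links(self):
        assert link_mother_infant(_bundle_with()).empty

    def test_infant_with_two_mothers_is_a_data_error(self):
        enr = pd.DataFrame(
            [
                _enrollment_row("M1", "F1", "mother", "2014-01", "2017-01"),
                _enrollment_row("M2", "F1", "mother", "2014-01", "2017-01"),
                _enrollment_row("I1", "F1", "infant", "2015-03", "2016-06", "2015-03"),
            ]
        )
        links = pd.DataFrame(
            [
                {"mother_id": "M1", "infant_id": "I1", "family_id": "F1"},
                {"mother_id": "M2", "infant_id": "I1", "family_id": "F1"},
            ]
        )
        with pytest.raises(DataError, match="I1"):
            link_mother_infant(_bundle_with(enr, links))


@pytest.fixture(scope="module")
def churny():
    cfg = SimConfig(
        n_mothers=800,
        seed=21,
        enrollment_churn=0.15,
        p_multiple_birth=0.05,
        p_chromosomal_abnormality=0.03,
    )
    bundle, truth = generate_bundle(cfg)
    links = link_mother_infant(bundle)
    episodes = build_episodes_for_bundle(bundle, links)
    retained, report = apply_eligibility(bundle, episodes, links)
    return bundle, truth, retained, report


class TestEligibility:
    def test_stage_counts_monotone_nonincreasing(self, churny):
        _, _, _, report = churny
        counts = [n for _, n in report.stage_counts]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_exclusion_reasons_account_for_all_drops(self, churny):
        _, _, retained, report = churny
        first = report.stage_counts[0][1]
        last = report.stage_counts[-1][1]
        assert retained["mother_id"].nunique() == last
        assert len(report.exclusions) == first - last

    def test_multiple_births_excluded(self, churny):
        _, truth, retained, report = churny
        twins = set(truth.mothers.loc[truth.mothers["multiple_birth"], "mother_id"])
        assert twins.isdisjoint(set(retained["mother_id"]))
        assert any(r == "multiple_birth" for r in report.exclusions.values())

    def test_chromosomal_infants_excluded(self, churny):
        bundle, truth, retained, _ = churny
        chrom = set(
            truth.mothers.loc[truth.mothers["chromosomal"], "infant_id"]
        )
        assert chrom.isdisjoint(set(retained["infant_id"]))

    def test_coverage_gap_reason_recorded(self, churny):
        _, _, _, report = churny
        assert any(r == "coverage_gap" for r in report.exclusions.values())

    def test_clean_generator_retains_every_linkable_mother(self):
        cfg = SimConfig(
            n_mothers=300,
            seed=8,
            enrollment_churn=0.0,
            p_multiple_birth=0.0,
            p_chromosomal_abnormality=0.0,
        )
        bundle, _ = generate_bundle(cfg)
        links = link_mother_infant(bundle)
        episodes = build_episodes_for_bundle(bundle, links)
        retained, _ = apply_eligibility(bundle, episodes, links)
        assert retained["mother_id"].nunique() == links["mother_id"].nunique() == 300


@pytest.fixture(scope="module")
def retained():
    bundle, truth = generate_bundle(SimConfig(n_mothers=400, seed=13))
    links = link_mother_infant(bundle)
    episodes = build_episodes_for_bundle(bundle, links)
    kept, _ = apply_eligibility(bundle, episodes, links)
    covs = derive_covariates(bundle, kept, default_covariate_codelists())
    return truth, kept, covs


class TestCovariates:
    @pytest.mark.parametrize(
        "age, band",
        [(22.0, "<=24"), (24.9, "<=24"), (25.0, "25-29"), (33.2, "30-34"), (35.0, ">=35")],
    )
    def test_age_bands(self, age, band):
        from kampopreg.cohort import _age_band

        assert _age_band(pd.Series([age])).astype(str).iloc[0] == band

    def test_preterm_threshold_at_259_days(self, retained):
        _, kept, covs = retained
        assert (covs["preterm_birth"] == (kept["gestation_days"] < 259)).all()

    def test_condition_flags_match_truth(self, retained):
        truth, _, covs = retained
        tm = truth.mothers.set_index("mother_id")
        for name in ("hypertension", "diabetes", "obesity", "epilepsy"):
            expected = tm.loc[covs["mother_id"], f"true_{name}"].to_numpy()
            assert (covs[name].to_numpy() == expected).all()

    def test_no_diagnoses_means_all_flags_false(self):
        enr = pd.DataFrame(
            [
                _enrollment_row("M1", "F1", "mother", "2013-01", "2017-01", "1985-05"),
                _enrollment_row("I1", "F1", "infant", "2015-03", "2016-06", "2015-03"),
            ]
        )
        links = pd.DataFrame([{"mother_id": "M1", "infant_id": "I1", "family_id": "F1"}])
        bundle = _bundle_with(enr, links)
        retained = pd.DataFrame(
            {
                "mother_id": ["M1"],
                "infant_id": ["I1"],
                "onset_date": [pd.Timestamp("2014-06-20")],
                "delivery_date": [pd.Timestamp("2015-03-15")],
                "gestation_days": [268],
            }
        )
        covs = derive_covariates(bundle, retained, default_covariate_codelists())
        for name in ("hypertension", "diabetes", "obesity", "epilepsy", "phenylketonuria"):
            assert not covs[name].iloc[0]
        assert covs["maternal_age_band"].astype(str).iloc[0] == "25-29"

    def test_missing_maternal_birth_month_flagged(self):
        enr = pd.DataFrame(
            [
                _enrollment_row("M1", "F1", "mother", "2013-01", "2017-01", None),
                _enrollment_row("I1", "F1", "infant", "2015-03", "2016-06", "2015-03"),
            ]
        )
        links = pd.DataFrame([{"mother_id": "M1", "infant_id": "I1", "family_id": "F1"}])
        bundle = _bundle_with(enr, links)
        retained = pd.DataFrame(
            {
                "mother_id": ["M1"],
                "infant_id": ["I1"],
                "onset_date": [pd.Timestamp("2014-06-20")],
                "delivery_date": [pd.Timestamp("2015-03-15")],
                "gestation_days": [268],
            }
        )
        covs = derive_covariates(bundle, retained, default_covariate_codelists())
        assert covs["missing_age"].iloc[0]
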