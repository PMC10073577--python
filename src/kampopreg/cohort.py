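"""Cohort construction: mother-infant linkage, eligibility, covariates.

Eligibility is applied in the attrition-flow order: a linkable infant
enrolled in its birth month, a datable pregnancy, continuous maternal
coverage from three months before onset through delivery (month
granularity), delivery year within the study window (first estimable
pregnancy kept), at least twelve months of infant coverage from the
birth month, no multiple birth, and no chromosomal-abnormality diagnosis
(Q90-Q99) in the infant.  Every drop is recorded with a reason and the
stage-by-stage survivor counts form the attrition report.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bundle import ClaimsBundle
from .codelists import CovariateCodeLists, code_matches
from .dating import build_episodes_frame, estimate_deliveries_frame, estimate_onsets_frame

logger = logging.getLogger(__name__)

PRETERM_THRESHOLD_DAYS = 259  # <37 weeks 0 days (WHO convention)
STUDY_YEARS = (2010, 2019)
AGE_BANDS = ("<=24", "25-29", "30-34", ">=35")
YEAR_BANDS = ("2010-2012", "2013-2015", "2016-2019")


class DataError(ValueError):
    """Structurally impossible claims data (e.g. an infant with two mothers)."""


def _month_ord(ym_strings: pd.Series) -> np.ndarray:
    """'YYYY-MM' -> integer month ordinal (year*12 + month), vectorised."""
    dt = pd.to_datetime(ym_strings.to_numpy(), format="%Y-%m")
    return (dt.year * 12 + dt.month).to_numpy()


@dataclass
class EligibilityReport:
    stage_counts: list[tuple[str, int]] = field(default_factory=list)
    exclusions: dict[str, str] = field(default_factory=dict)

    def record(self, label: str, remaining: int) -> None:
        if self.stage_counts and remaining > self.stage_counts[-1][1]:
            raise ValueError("stage counts must be non-increasing")
        self.stage_counts.append((label, remaining))

    def to_dict(self) -> dict:
        reasons = (
            pd.Series(list(self.exclusions.values())).value_counts().sort_index()
            if self.exclusions
            else pd.Series(dtype=int)
        )
        return {
            "stages": [
                {"criterion": c, "n_remaining": int(n)} for c, n in self.stage_counts
            ],
            "n_excluded_by_reason": {k: int(v) for k, v in reasons.items()},
        }


def link_mother_infant(bundle: ClaimsBundle) -> pd.DataFrame:
    """Links whose infant was enrolled in its own birth month.

    Raises :class:`DataError` when an infant is linked to two mothers.
    """
    dup = bundle.links["infant_id"][bundle.links["infant_id"].duplicated()]
    if not dup.empty:
        raise DataError(f"infant linked to multiple mothers: {sorted(set(dup))[:5]}")
    inf = bundle.enrollment[bundle.enrollment["role"] == "infant"]
    merged = bundle.links.merge(
        inf[["person_id", "coverage_start_month", "coverage_end_month", "birth_year_month"]],
        left_on="infant_id",
        right_on="person_id",
        how="inner",
    )
    kept = merged[merged["coverage_start_month"] == merged["birth_year_month"]]
    return kept[
        ["mother_id", "infant_id", "family_id", "birth_year_month", "coverage_end_month"]
    ].rename(columns={"coverage_end_month": "infant_coverage_end_month"})


def apply_eligibility(
    bundle: ClaimsBundle,
    episodes: pd.DataFrame,
    links: pd.DataFrame,
) -> tuple[pd.DataFrame, EligibilityReport]:
    """Apply the eligibility cascade; returns (retained pairs, report).

    ``episodes`` is the frame from :func:`~kampopreg.dating.build_episodes_frame`
    (indexed by mother_id); ``links`` the output of :func:`link_mother_infant`.
    The retained frame has one row per mother joined with her episode.
    """
    report = EligibilityReport()
    pairs = links.copy()
    report.record(
        "linked mother-infant pairs (infant enrolled in birth month)",
        pairs["mother_id"].nunique(),
    )

    def drop(mask: pd.Series, reason: str, label: str) -> None:
        nonlocal pairs
        for m in pairs.loc[mask, "mother_id"]:
            report.exclusions[m] = reason
        pairs = pairs[~mask]
        report.record(label, pairs["mother_id"].nunique())

    drop(
        ~pairs["mother_id"].isin(episodes.index),
        "undatable",
        "datable pregnancy episode",
    )
    pairs = pairs.merge(episodes, left_on="mother_id", right_index=True, how="left")

    enr_m = bundle.enrollment[bundle.enrollment["role"] == "mother"].set_index("person_id")
    cov_start = _month_ord(enr_m.reindex(pairs["mother_id"])["coverage_start_month"])
    cov_end = _month_ord(enr_m.reindex(pairs["mother_id"])["coverage_end_month"])
    lookback = pairs["onset_date"] - pd.Timedelta(days=90)
    need_start = (lookback.dt.year * 12 + lookback.dt.month).to_numpy()
    need_end = (
        pairs["delivery_date"].dt.year * 12 + pairs["delivery_date"].dt.month
    ).to_numpy()
    ok = (cov_start <= need_start) & (cov_end >= need_end)
    drop(
        pd.Series(~ok, index=pairs.index),
        "coverage_gap",
        "maternal coverage from onset - 3 months through delivery",
    )

    year = pairs["delivery_date"].dt.year
    drop(
        ~year.between(*STUDY_YEARS),
        "outside_study_years",
        f"delivery year {STUDY_YEARS[0]}-{STUDY_YEARS[1]}",
    )
    # One estimable episode per mother by construction (the dating stage
    # keeps a single onset/delivery pair), so "first pregnancy in the
    # window" is enforced upstream; the stage is still reported.
    report.record("first pregnancy in the study window", pairs["mother_id"].nunique())

    months_cov = (
        _month_ord(pairs["infant_coverage_end_month"])
        - _month_ord(pairs["birth_year_month"])
        + 1
    )
    drop(
        pd.Series(months_cov < 12, index=pairs.index),
        "infant_coverage_lt_12m",
        "infant covered >= 12 months from birth month",
    )

    multi = pairs["mother_id"].value_counts()
    drop(
        pairs["mother_id"].isin(multi[multi > 1].index),
        "multiple_birth",
        "singleton deliveries only",
    )

    chrom = bundle.diagnoses[code_matches(bundle.diagnoses["icd10_code"], ["Q9"])]
    drop(
        pairs["infant_id"].isin(set(chrom["person_id"])),
        "chromosomal",
        "no chromosomal abnormality (Q90-Q99) in infant",
    )
    return pairs.reset_index(drop=True), report


def _age_band(age: pd.Series) -> pd.Series:
    # ordered categorical so the youngest band is the model reference
    return pd.cut(age, bins=[-np.inf, 25, 30, 35, np.inf], right=False, labels=AGE_BANDS)


def _year_band(year: pd.Series) -> pd.Series:
    return pd.cut(year, bins=[2009, 2012, 2015, 2019], labels=YEAR_BANDS)


def derive_covariates(
    bundle: ClaimsBundle,
    retained: pd.DataFrame,
    codelists: CovariateCodeLists,
    exposure_flags: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Covariate set for each retained mother-infant pair.

    Condition flags are true when any matching diagnosis falls between
    onset - 3 months and delivery; ``teratogen_rx_t1`` comes from the
    exposure flags when supplied.  Mothers without a recorded birth
    year-month are flagged ``missing_age`` (excluded downstream).
    """
    out = retained[["mother_id", "infant_id"]].copy()
    enr_m = bundle.enrollment[bundle.enrollment["role"] == "mother"].set_index("person_id")
    mb = enr_m.reindex(retained["mother_id"])["birth_year_month"]
    out["missing_age"] = mb.isna().to_numpy()
    birth_ts = pd.to_datetime(
        np.where(mb.isna(), "2000-01", mb.to_numpy()), format="%Y-%m"
    ) + pd.Timedelta(days=14)
    age = (retained["delivery_date"].to_numpy() - birth_ts.to_numpy()).astype(
        "timedelta64[D]"
    ).astype(float) / 365.25
    out["maternal_age_years"] = np.round(age, 2)
    out["maternal_age_band"] = _age_band(pd.Series(age, index=out.index))
    out.loc[out["missing_age"], ["maternal_age_years"]] = np.nan
    out["delivery_year"] = retained["delivery_date"].dt.year.to_numpy()
    out["delivery_year_band"] = _year_band(out["delivery_year"])
    out["gestation_days"] = retained["gestation_days"].to_numpy()
    out["preterm_birth"] = out["gestation_days"] < PRETERM_THRESHOLD_DAYS

    window_lo = retained.set_index("mother_id")["onset_date"] - pd.Timedelta(days=90)
    window_hi = retained.set_index("mother_id")["delivery_date"]
    dx = bundle.diagnoses.merge(
        pd.DataFrame({"lo": window_lo, "hi": window_hi}),
        left_on="person_id",
        right_index=True,
        how="inner",
    )
    in_window = (dx["diagnosis_date"] >= dx["lo"]) & (dx["diagnosis_date"] <= dx["hi"])
    dx = dx[in_window]
    for name, prefixes in codelists.prefixes.items():
        hits = dx.loc[code_matches(dx["icd10_code"], prefixes), "person_id"].unique()
        out[name] = out["mother_id"].isin(hits).to_numpy()
    if exposure_flags is not None and "teratogen_t1" in exposure_flags:
        out["teratogen_rx_t1"] = (
            exposure_flags["teratogen_t1"].reindex(out["mother_id"]).fillna(False).to_numpy()
        )
    else:
        out["teratogen_rx_t1"] = False
    return out


def build_episodes_for_bundle(bundle: ClaimsBundle, links: pd.DataFrame) -> pd.DataFrame:
    """Dating entry point for a whole bundle: onset + delivery -> episodes.

    Mothers absent from ``links`` cannot receive a delivery estimate (no
    infant birth month) and are omitted, mirroring the study's linkage
    requirement.
    """
    onsets = estimate_onsets_frame(bundle.diagnoses)
    birth_ym = links.drop_duplicates("mother_id").set_index("mother_id")["birth_year_month"]
    deliveries = estimate_deliveries_frame(bundle.delivery_entries, birth_ym)
    return build_episodes_frame(onsets, deliveries)
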