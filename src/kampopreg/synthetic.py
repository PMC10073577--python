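"""Synthetic claims generator with known ground truth.

The real study database (proprietary Japanese employment-based insurance
claims) cannot be redistributed, so every pipeline stage is exercised on
synthetic bundles that emulate its structure: month-granular enrollment,
GA-annotated prenatal visits, three-tier delivery evidence (about half of
mothers have a delivery-specific procedure entry, a tenth another
delivery-related entry, and the rest none, forcing the month-midpoint
fallback), prescriptions with days-of-supply and occasionally missing
dispensing dates, and infant malformation diagnoses.

Ground truth (true onset/delivery dates, true per-trimester exposure,
true covariates and outcome) is recorded before any missingness is
injected, so parameter-recovery and dating-accuracy tests are exact.

Default parameters are the study conditions: gestation length
N(270.7, 12.9) truncated to [119, 294] days; delivery-evidence shares
0.494/0.094; per-class, per-trimester prescription prevalences from the
study's laxative table; a 6.1% malformation base rate entering the
outcome model as ``expit(logit(rate) + log_or_krr * krr_t1 + covariate
effects)``.  Within a drug class, per-trimester prescriptions are
correlated through a shared "user" indicator whose probability is solved
so that both the per-trimester and the any-trimester prevalences match
their targets.
"""
from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import optimize, special, stats

from .bundle import ClaimsBundle
from .codelists import ORGAN_SYSTEMS

DRUG_CLASSES = ("mgo", "krr", "sg", "daikenchuto")
TRIMESTERS = ("t1", "t2", "t3")

# Laxative-table prevalences: any trimester, then first/second/third.
_DEFAULT_RX = {
    "mgo": {"overall": 0.3460, "t1": 0.1390, "t2": 0.2128, "t3": 0.2245},
    "sg": {"overall": 0.0735, "t1": 0.0211, "t2": 0.0286, "t3": 0.0486},
    "krr": {"overall": 0.0133, "t1": 0.0063, "t2": 0.0061, "t3": 0.0060},
    "daikenchuto": {"overall": 0.0051, "t1": 0.0018, "t2": 0.0020, "t3": 0.0026},
}

# Relative frequencies of the 17 rhubarb-rhizome products (overall counts).
_KRR_PRODUCT_WEIGHTS = {
    "mashiningan": 321,
    "daiokanzoto": 198,
    "otsujito": 160,
    "bofutsushosan": 111,
    "tokakujokito": 74,
    "keishikashakuyakudaioto": 64,
    "junchoto": 51,
    "crude_daio": 30,
    "tsudosan": 10,
    "choijokito": 8,
    "jidabokuippo": 8,
    "daisaikoto": 8,
    "daiobotampito": 5,
    "sanoshashinto": 4,
    "inchinkoto": 3,
    "jizusoippo": 1,
    "daijokito": 1,
}

# Organ-system mix of malformations (comparator-group counts) and one
# representative major ICD-10 code per system, chosen to match the default
# code list and avoid its minor-anomaly exclusions.
_MCM_SYSTEM_WEIGHTS = {
    "nervous": 43,
    "eye_ear_face_neck": 13,
    "circulatory": 248,
    "respiratory": 34,
    "cleft_lip_palate": 15,
    "digestive": 47,
    "genital": 44,
    "urinary": 48,
    "musculoskeletal": 216,
    "other": 27,
}
_MCM_SYSTEM_CODES = {
    "nervous": "Q03.9",
    "eye_ear_face_neck": "Q11.2",
    "circulatory": "Q21.0",
    "respiratory": "Q33.0",
    "cleft_lip_palate": "Q35.9",
    "digestive": "Q42.3",
    "genital": "Q54.1",
    "urinary": "Q61.4",
    "musculoskeletal": "Q71.3",
    "other": "Q87.0",
}

_DEFAULT_COVARIATES = {
    "hypertension": 0.017,
    "diabetes": 0.045,
    "obesity": 0.007,
    "epilepsy": 0.009,
    "phenylketonuria": 0.0002,
    "teratogen_rx_t1": 0.004,
    "caesarean": 0.227,
}
_COVARIATE_DX_CODES = {
    "hypertension": "I10",
    "diabetes": "E11.9",
    "obesity": "E66.9",
    "epilepsy": "G40.9",
    "phenylketonuria": "E70.0",
}


class SimConfig(BaseModel):
    """Generator parameters; defaults are the emulated study conditions."""

    n_mothers: int = Field(ge=1)
    seed: int = 0
    gestation_mean_days: float = 270.7
    gestation_sd_days: float = Field(default=12.9, gt=0)
    gestation_min_days: int = Field(default=119, ge=1)
    gestation_max_days: int = Field(default=294, le=294)
    p_delivery_entry_specific: float = Field(default=0.494, ge=0, le=1)
    p_delivery_entry_other: float = Field(default=0.094, ge=0, le=1)
    ga_visit_schedule: tuple[int, ...] = (8, 12, 20, 30, 38)
    p_missing_dispense_date: float = Field(default=0.05, ge=0, le=1)
    rx_propensity: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_RX.items()}
    )
    krr_product_weights: dict[str, float] = Field(
        default_factory=lambda: dict(_KRR_PRODUCT_WEIGHTS)
    )
    mcm_base_rate: float = Field(default=0.061, ge=0, le=1)
    true_log_or_krr: float = 0.0
    covariate_prevalences: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_COVARIATES)
    )
    covariate_log_or: dict[str, float] = Field(
        default_factory=lambda: {"preterm_birth": math.log(1.5), "obesity": math.log(1.5)}
    )
    p_multiple_birth: float = Field(default=0.01, ge=0, le=1)
    p_chromosomal_abnormality: float = Field(default=0.005, ge=0, le=1)
    enrollment_churn: float = Field(default=0.02, ge=0, le=1)
    p_as_needed: float = Field(default=0.05, ge=0, le=1)
    extra_rx_rate: float = Field(default=0.5, ge=0)
    maternal_age_mean: float = 32.3
    maternal_age_sd: float = 4.6
    delivery_window: tuple[dt.date, dt.date] = (dt.date(2011, 1, 1), dt.date(2018, 12, 31))

    @field_validator("rx_propensity", "covariate_prevalences")
    @classmethod
    def _probs_in_unit_interval(cls, v, info):
        flat = v.values() if info.field_name == "covariate_prevalences" else (
            x for d in v.values() for x in d.values()
        )
        for p in flat:
            if not 0 <= p <= 1:
                raise ValueError(f"{info.field_name}: probability {p} outside [0, 1]")
        return v

    @model_validator(mode="after")
    def _gestation_bounds(self):
        if self.gestation_min_days > self.gestation_max_days:
            raise ValueError("gestation_min_days exceeds gestation_max_days")
        if self.p_delivery_entry_specific + self.p_delivery_entry_other > 1:
            raise ValueError("p_delivery_entry_specific + p_delivery_entry_other exceeds 1")
        return self


@dataclass
class SimTruth:
    """Per-mother ground truth recorded before missingness injection."""

    mothers: pd.DataFrame

    def to_json(self) -> str:
        df = self.mothers.copy()
        for c in ("true_onset_date", "true_delivery_date"):
            df[c] = pd.to_datetime(df[c]).dt.strftime("%Y-%m-%d")
        return json.dumps(df.to_dict(orient="records"), indent=None, default=str)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        df = pd.DataFrame(json.loads(text))
        for c in ("true_onset_date", "true_delivery_date"):
            df[c] = pd.to_datetime(df[c])
        return cls(df)


@lru_cache(maxsize=None)
def _solve_user_prob(pt: tuple[float, ...], p_any: float) -> float:
    """Probability of the latent "user" indicator in the one-factor model.

    Given per-trimester targets ``pt`` and an any-trimester target
    ``p_any``, solve pi so that with trimester draws Bernoulli(pt/pi)
    conditional on user ~ Bernoulli(pi), both marginals are matched.
    Falls back to independence (pi = 1) when p_any is not reachable.
    """
    arr = np.asarray(pt, dtype=float)
    if p_any <= 0 or arr.sum() == 0:
        return 1.0

    def gap(pi: float) -> float:
        return pi * (1 - np.prod(1 - arr / pi)) - p_any

    lo = float(arr.max()) + 1e-12
    if gap(1.0) < 0 or gap(lo) > 0:
        return 1.0
    return float(optimize.brentq(gap, lo, 1.0))


def _ym_series(dates: np.ndarray) -> np.ndarray:
    return np.datetime_as_string(dates.astype("datetime64[M]"), unit="M")


def _shift_months(dates: np.ndarray, k: np.ndarray | int) -> np.ndarray:
    return (dates.astype("datetime64[M]") + np.asarray(k, dtype="timedelta64[M]")).astype(str)


def generate_bundle(config: SimConfig) -> tuple[ClaimsBundle, SimTruth]:
    """Generate one claims bundle plus its ground truth, deterministically."""
    cfg = config
    n = cfg.n_mothers
    rng = np.random.default_rng(cfg.seed)

    mother_id = np.array([f"M{i:06d}" for i in range(n)])
    infant_id = np.array([f"I{i:06d}" for i in range(n)])
    family_id = np.array([f"F{i:06d}" for i in range(n)])

    # --- true pregnancy dates -------------------------------------------
    a = (cfg.gestation_min_days - cfg.gestation_mean_days) / cfg.gestation_sd_days
    b = (cfg.gestation_max_days - cfg.gestation_mean_days) / cfg.gestation_sd_days
    gest = np.rint(
        stats.truncnorm.rvs(
            a, b, loc=cfg.gestation_mean_days, scale=cfg.gestation_sd_days,
            size=n, random_state=rng,
        )
    ).astype(int)
    lo_ord = np.datetime64(cfg.delivery_window[0], "D").astype(int)
    hi_ord = np.datetime64(cfg.delivery_window[1], "D").astype(int)
    delivery = rng.integers(lo_ord, hi_ord + 1, size=n).astype("datetime64[D]")
    onset = delivery - gest.astype("timedelta64[D]")

    age = np.clip(rng.normal(cfg.maternal_age_mean, cfg.maternal_age_sd, n), 18.0, 48.0)
    mother_birth = delivery - np.rint(age * 365.25).astype("timedelta64[D]")

    # --- delivery evidence tier -----------------------------------------
    u = rng.random(n)
    has_specific = u < cfg.p_delivery_entry_specific
    has_other = (~has_specific) & (
        u < cfg.p_delivery_entry_specific + cfg.p_delivery_entry_other
    )
    entry_tier = np.where(has_specific, "specific", np.where(has_other, "other", "none"))

    # --- prescriptions ---------------------------------------------------
    trim_lo = {"t1": np.zeros(n, int), "t2": np.full(n, 98), "t3": np.full(n, 196)}
    trim_hi = {
        "t1": np.minimum(97, gest),
        "t2": np.minimum(195, gest),
        "t3": gest,
    }
    true_flags: dict[str, np.ndarray] = {}
    rx_parts: list[dict[str, np.ndarray]] = []
    krr_names = np.array(list(cfg.krr_product_weights))
    krr_w = np.array(list(cfg.krr_product_weights.values()), float)
    krr_w = krr_w / krr_w.sum()
    class_code = {"mgo": "A02AA02", "sg": "A06AB06", "daikenchuto": "daikenchuto"}

    for cls_name in DRUG_CLASSES:
        probs = cfg.rx_propensity.get(cls_name, {"overall": 0.0, "t1": 0.0, "t2": 0.0, "t3": 0.0})
        pt = tuple(probs[t] for t in TRIMESTERS)
        pi = _solve_user_prob(pt, probs.get("overall", 0.0))
        user = rng.random(n) < pi
        for t, p_t in zip(TRIMESTERS, pt):
            flag = user & (rng.random(n) < (p_t / pi if pi > 0 else 0.0))
            if t == "t3":
                flag &= gest >= 196
            true_flags[f"{cls_name}_{t}"] = flag
            idx = np.flatnonzero(flag)
            if idx.size == 0:
                continue
            counts = 1 + rng.poisson(cfg.extra_rx_rate, idx.size)
            rep = np.repeat(idx, counts)
            m = rep.size
            supply = rng.choice([7, 14, 28, 30], size=m, p=[0.3, 0.4, 0.15, 0.15])
            lo = trim_lo[t][rep]
            hi = np.maximum(lo, trim_hi[t][rep] - supply + 1)
            offset = lo + (rng.random(m) * (hi - lo + 1)).astype(int)
            date = onset[rep] + offset.astype("timedelta64[D]")
            if cls_name == "krr":
                code = rng.choice(krr_names, size=m, p=krr_w)
            else:
                code = np.full(m, class_code[cls_name])
            rx_parts.append(
                {
                    "person_id": mother_id[rep],
                    "drug_code": code,
                    "true_date": date,
                    "days_of_supply": supply,
                    "as_needed": rng.random(m) < cfg.p_as_needed,
                }
            )

    # teratogen prescriptions, always inside the first trimester
    terat_flag = rng.random(n) < cfg.covariate_prevalences.get("teratogen_rx_t1", 0.0)
    idx = np.flatnonzero(terat_flag)
    if idx.size:
        offset = (rng.random(idx.size) * 84).astype(int)
        rx_parts.append(
            {
                "person_id": mother_id[idx],
                "drug_code": rng.choice(
                    ["N03AG01", "D10BA01", "L04AX03", "B01AA03", "L04AX02"], idx.size
                ),
                "true_date": onset[idx] + offset.astype("timedelta64[D]"),
                "days_of_supply": np.full(idx.size, 14),
                "as_needed": np.zeros(idx.size, bool),
            }
        )

    if rx_parts:
        cat = {
            k: np.concatenate([p[k] for p in rx_parts]) for k in rx_parts[0]
        }
        m = len(cat["person_id"])
        missing = rng.random(m) < cfg.p_missing_dispense_date
        keep_admission = missing & (rng.random(m) < 0.5)
        true_date = cat["true_date"].astype("datetime64[D]")
        rx = pd.DataFrame(
            {
                "person_id": cat["person_id"],
                "drug_code": cat["drug_code"],
                "dispense_date": pd.to_datetime(
                    np.where(missing, np.datetime64("NaT"), true_date)
                ),
                "admission_date": pd.to_datetime(
                    np.where(keep_admission, true_date, np.datetime64("NaT"))
                ),
                "claim_year_month": _ym_series(true_date),
                "days_of_supply": cat["days_of_supply"].astype(np.int64),
                "as_needed": cat["as_needed"],
            }
        )
        rx = rx.sort_values(
            ["person_id", "claim_year_month", "drug_code", "days_of_supply"],
            kind="stable",
            ignore_index=True,
        )
    else:
        rx = pd.DataFrame(
            columns=[
                "person_id",
                "drug_code",
                "dispense_date",
                "admission_date",
                "claim_year_month",
                "days_of_supply",
                "as_needed",
            ]
        )

    # --- covariates and outcome -----------------------------------------
    cov_flags: dict[str, np.ndarray] = {"teratogen_rx_t1": terat_flag}
    for name in ("hypertension", "diabetes", "obesity", "epilepsy", "phenylketonuria", "caesarean"):
        cov_flags[name] = rng.random(n) < cfg.covariate_prevalences.get(name, 0.0)
    preterm = gest < 259
    cov_flags["preterm_birth"] = preterm

    xb = special.logit(cfg.mcm_base_rate) + cfg.true_log_or_krr * true_flags["krr_t1"]
    for name, beta in cfg.covariate_log_or.items():
        if name in cov_flags:
            xb = xb + beta * cov_flags[name]
    mcm = rng.random(n) < special.expit(xb)
    sys_names = np.array(ORGAN_SYSTEMS)
    sys_w = np.array([_MCM_SYSTEM_WEIGHTS[s] for s in sys_names], float)
    mcm_system = np.where(
        mcm, rng.choice(sys_names, size=n, p=sys_w / sys_w.sum()), ""
    )

    multiple = rng.random(n) < cfg.p_multiple_birth
    chromosomal = rng.random(n) < cfg.p_chromosomal_abnormality
    churn = rng.random(n) < cfg.enrollment_churn
    churn_mother = churn & (rng.random(n) < 0.5)
    churn_infant = churn & ~churn_mother

    # --- diagnoses -------------------------------------------------------
    dx_parts: list[dict[str, np.ndarray]] = []

    def add_dx(person, code, date, ga_weeks=None, ga_days=None):
        k = len(person)
        dx_parts.append(
            {
                "person_id": np.asarray(person),
                "icd10_code": np.full(k, code) if np.isscalar(code) else np.asarray(code),
                "diagnosis_date": np.asarray(date, dtype="datetime64[D]"),
                "ga_weeks": np.full(k, np.nan) if ga_weeks is None else np.asarray(ga_weeks, float),
                "ga_days": np.full(k, np.nan) if ga_days is None else np.asarray(ga_days, float),
            }
        )

    for w in cfg.ga_visit_schedule:
        mask = gest >= 7 * w
        idx = np.flatnonzero(mask)
        if idx.size:
            add_dx(
                mother_id[idx],
                "Z34.9",
                onset[idx] + np.timedelta64(7 * w, "D"),
                ga_weeks=np.full(idx.size, w),
                ga_days=np.zeros(idx.size, int),
            )

    for name, code in _COVARIATE_DX_CODES.items():
        idx = np.flatnonzero(cov_flags[name])
        if idx.size:
            span = gest[idx] + 90
            off = (rng.random(idx.size) * (span + 1)).astype(int)
            add_dx(mother_id[idx], code, onset[idx] - np.timedelta64(90, "D") + off.astype("timedelta64[D]"))
    idx = np.flatnonzero(cov_flags["caesarean"])
    if idx.size:
        add_dx(mother_id[idx], "O82", delivery[idx])
    # incidental maternal constipation diagnoses (noise)
    idx = np.flatnonzero(rng.random(n) < 0.25)
    if idx.size:
        off = (rng.random(idx.size) * (gest[idx] + 1)).astype(int)
        add_dx(mother_id[idx], "K59.0", onset[idx] + off.astype("timedelta64[D]"))

    birth_month_start = delivery.astype("datetime64[M]").astype("datetime64[D]")
    idx = np.flatnonzero(mcm)
    if idx.size:
        codes = np.array([_MCM_SYSTEM_CODES[s] for s in mcm_system[idx]])
        off = (rng.random(idx.size) * 331).astype(int)
        add_dx(infant_id[idx], codes, birth_month_start[idx] + off.astype("timedelta64[D]"))
    idx = np.flatnonzero(chromosomal)
    if idx.size:
        add_dx(infant_id[idx], "Q90.9", birth_month_start[idx] + np.timedelta64(60, "D"))
    # infant noise: minor anomaly and a common infection code
    idx = np.flatnonzero(rng.random(n) < 0.03)
    if idx.size:
        off = (rng.random(idx.size) * 331).astype(int)
        add_dx(infant_id[idx], "Q82.5", birth_month_start[idx] + off.astype("timedelta64[D]"))
    idx = np.flatnonzero(rng.random(n) < 0.20)
    if idx.size:
        off = (rng.random(idx.size) * 331).astype(int)
        add_dx(infant_id[idx], "J06.9", birth_month_start[idx] + off.astype("timedelta64[D]"))

    dx_cat = {k: np.concatenate([p[k] for p in dx_parts]) for k in dx_parts[0]}
    diagnoses = pd.DataFrame(
        {
            "person_id": dx_cat["person_id"],
            "icd10_code": dx_cat["icd10_code"],
            "diagnosis_date": pd.to_datetime(dx_cat["diagnosis_date"]),
            "ga_weeks": pd.Series(dx_cat["ga_weeks"]).astype("Int64"),
            "ga_days": pd.Series(dx_cat["ga_days"]).astype("Int64"),
        }
    ).sort_values(
        ["person_id", "diagnosis_date", "icd10_code"], kind="stable", ignore_index=True
    )

    # --- delivery entries -------------------------------------------------
    kinds = np.where(has_specific, "specific_procedure", "other_delivery_related")
    mask = has_specific | has_other
    delivery_entries = pd.DataFrame(
        {
            "person_id": mother_id[mask],
            "entry_date": pd.to_datetime(delivery[mask]),
            "entry_kind": kinds[mask],
        }
    ).sort_values(["person_id"], kind="stable", ignore_index=True)

    # --- enrollment and links ---------------------------------------------
    birth_ym = _ym_series(delivery)
    pre_start = (onset - np.timedelta64(90, "D")).astype("datetime64[M]")
    extra_before = rng.integers(0, 13, n)
    mother_start = (pre_start - extra_before.astype("timedelta64[M]")).astype(str)
    mother_start = np.where(
        churn_mother, (pre_start + np.timedelta64(2, "M")).astype(str), mother_start
    )
    mother_end = _shift_months(delivery, rng.integers(1, 25, n))
    infant_end_off = np.where(churn_infant, rng.integers(2, 11, n), rng.integers(11, 36, n))
    infant_end = _shift_months(delivery, infant_end_off)

    sex_inf = rng.choice(["M", "F"], n)
    mothers_enr = pd.DataFrame(
        {
            "person_id": mother_id,
            "family_id": family_id,
            "role": "mother",
            "coverage_start_month": mother_start,
            "coverage_end_month": mother_end,
            "birth_year_month": _ym_series(mother_birth),
            "sex": "F",
        }
    )
    infants_enr = pd.DataFrame(
        {
            "person_id": infant_id,
            "family_id": family_id,
            "role": "infant",
            "coverage_start_month": birth_ym,
            "coverage_end_month": infant_end,
            "birth_year_month": birth_ym,
            "sex": sex_inf,
        }
    )
    links = pd.DataFrame(
        {"mother_id": mother_id, "infant_id": infant_id, "family_id": family_id}
    )
    idx = np.flatnonzero(multiple)
    if idx.size:
        twin_id = np.array([f"{i}X" for i in infant_id[idx]])
        twins_enr = infants_enr.iloc[idx].copy()
        twins_enr["person_id"] = twin_id
        twins_enr["sex"] = rng.choice(["M", "F"], idx.size)
        infants_enr = pd.concat([infants_enr, twins_enr], ignore_index=True)
        links = pd.concat(
            [
                links,
                pd.DataFrame(
                    {
                        "mother_id": mother_id[idx],
                        "infant_id": twin_id,
                        "family_id": family_id[idx],
                    }
                ),
            ],
            ignore_index=True,
        )
    enrollment = pd.concat([mothers_enr, infants_enr], ignore_index=True).sort_values(
        "person_id", kind="stable", ignore_index=True
    )
    links = links.sort_values("mother_id", kind="stable", ignore_index=True)

    bundle = ClaimsBundle(
        enrollment=enrollment,
        diagnoses=diagnoses,
        prescriptions=rx,
        delivery_entries=delivery_entries,
        links=links,
    )
    bundle.validate()

    truth_df = pd.DataFrame(
        {
            "mother_id": mother_id,
            "infant_id": infant_id,
            "true_onset_date": pd.to_datetime(onset),
            "true_delivery_date": pd.to_datetime(delivery),
            "gestation_days": gest,
            "delivery_entry": entry_tier,
            "maternal_age": np.round(age, 2),
            "true_mcm": mcm,
            "mcm_system": mcm_system,
            "multiple_birth": multiple,
            "chromosomal": chromosomal,
            "churned": churn,
        }
    )
    for key, flag in true_flags.items():
        truth_df[f"true_{key}"] = flag
    for name, flag in cov_flags.items():
        truth_df[f"true_{name}"] = flag
    return bundle, SimTruth(truth_df)
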