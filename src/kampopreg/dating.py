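"""Pregnancy episode dating from claims.

Neither pregnancy onset nor the delivery date is recorded directly in
Japanese health-insurance claims.  Both are reconstructed:

* **Onset** — prenatal-care diagnoses carry a gestational-age (GA)
  annotation (weeks + days).  Onset is the diagnosis date minus the
  annotated GA; when a woman has several GA-annotated visits the most
  recent one is used, since late-pregnancy dating is the most accurate.
* **Delivery** — a delivery-specific procedure entry if present (latest
  date when several), else any other delivery-related entry, else the
  15th of the infant's birth month (birth dates are only recorded at
  month granularity).

Gestation is capped at 294 days: when the estimated span exceeds the cap,
onset is moved to 294 days before delivery.  Trimesters are gestational
days 0–97 (to week 13 day 6), 98–195 (week 14 day 0 to week 27 day 6)
and 196 onwards (week 28 day 0 to delivery), inclusive at both ends.
"""
from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._dates import month_mid, months_between, ym

logger = logging.getLogger(__name__)

MAX_GESTATION_DAYS = 294
T1_LAST_DAY = 97   # week 13, day 6
T2_LAST_DAY = 195  # week 27, day 6
T3_FIRST_DAY = 196  # week 28, day 0


class UndatablePregnancyError(ValueError):
    """No GA-annotated diagnosis exists; the pregnancy cannot be dated."""


class InvalidEpisodeError(ValueError):
    """Onset after delivery — no valid episode can be built."""


class DeliveryMethod(str, Enum):
    specific_entry = "specific_entry"
    other_entry = "other_entry"
    month_midpoint = "month_midpoint"


class Trimester(str, Enum):
    pre_pregnancy = "pre_pregnancy"
    first = "first"
    second = "second"
    third = "third"
    post_delivery = "post_delivery"


@dataclass(frozen=True)
class GADiagnosis:
    """A diagnosis carrying a gestational-age annotation."""

    diagnosis_date: dt.date
    ga_weeks: int
    ga_days: int = 0  # weeks-only records imply day 0

    def __post_init__(self) -> None:
        if not (0 <= self.ga_weeks <= 45):
            raise ValueError(f"ga_weeks out of range: {self.ga_weeks}")
        if not (0 <= self.ga_days <= 6):
            raise ValueError(f"ga_days out of range: {self.ga_days}")

    @property
    def ga_total_days(self) -> int:
        return 7 * self.ga_weeks + self.ga_days


@dataclass(frozen=True)
class DeliveryEstimate:
    delivery_date: dt.date
    method: DeliveryMethod

    def __post_init__(self) -> None:
        if self.method is DeliveryMethod.month_midpoint and self.delivery_date.day != 15:
            raise ValueError("month_midpoint estimates must fall on the 15th")


Window = Optional[tuple[dt.date, dt.date]]


@dataclass(frozen=True)
class PregnancyEpisode:
    """A dated pregnancy with its trimester windows.

    Windows are closed intervals of calendar days; the second and third
    windows are ``None`` when gestation ends before they start.
    """

    onset_date: dt.date
    delivery_estimate: DeliveryEstimate
    capped_294: bool
    t1: Window
    t2: Window
    t3: Window

    @property
    def delivery_date(self) -> dt.date:
        return self.delivery_estimate.delivery_date

    @property
    def gestation_days(self) -> int:
        return (self.delivery_date - self.onset_date).days


def estimate_onset(ga_diagnoses: Sequence[GADiagnosis]) -> dt.date:
    """Onset from the most recent GA-annotated diagnosis.

    Tie-break when two diagnoses share the latest date but disagree on GA:
    the smaller implied gestation (later onset) wins — conservative for
    first-trimester exposure windows — and the conflict is logged.
    """
    if not ga_diagnoses:
        raise UndatablePregnancyError("no GA-annotated diagnoses")
    latest = max(d.diagnosis_date for d in ga_diagnoses)
    at_latest = [d for d in ga_diagnoses if d.diagnosis_date == latest]
    if len({d.ga_total_days for d in at_latest}) > 1:
        logger.warning(
            "conflicting GA annotations on %s; using the smallest (later onset)", latest
        )
    chosen = min(at_latest, key=lambda d: d.ga_total_days)
    return chosen.diagnosis_date - dt.timedelta(days=chosen.ga_total_days)


def estimate_delivery(
    delivery_entries: Iterable[tuple[dt.date, str]],
    infant_birth_year_month: str,
) -> DeliveryEstimate:
    """Delivery date via the three-tier rule.

    ``delivery_entries`` are ``(entry_date, entry_kind)`` with kind in
    ``{"specific_procedure", "other_delivery_related"}``.  Entries dated
    outside the infant's birth month ±1 month are ignored with a warning.
    """
    specific: list[dt.date] = []
    other: list[dt.date] = []
    for entry_date, kind in delivery_entries:
        if abs(months_between(infant_birth_year_month, ym(entry_date))) > 1:
            logger.warning(
                "delivery entry %s outside birth month %s ±1; ignored",
                entry_date,
                infant_birth_year_month,
            )
            continue
        if kind == "specific_procedure":
            specific.append(entry_date)
        elif kind == "other_delivery_related":
            other.append(entry_date)
        else:
            raise ValueError(f"unknown delivery entry kind: {kind!r}")
    if specific:
        return DeliveryEstimate(max(specific), DeliveryMethod.specific_entry)
    if other:
        return DeliveryEstimate(max(other), DeliveryMethod.other_entry)
    return DeliveryEstimate(month_mid(infant_birth_year_month), DeliveryMethod.month_midpoint)


def build_episode(onset: dt.date, delivery: DeliveryEstimate) -> PregnancyEpisode:
    """Assemble the episode, applying the 294-day cap before windowing."""
    dd = delivery.delivery_date
    if onset > dd:
        raise InvalidEpisodeError(f"onset {onset} after delivery {dd}")
    capped = False
    if (dd - onset).days > MAX_GESTATION_DAYS:
        onset = dd - dt.timedelta(days=MAX_GESTATION_DAYS)
        capped = True
    gest = (dd - onset).days

    def window(first_day: int, last_day: int) -> Window:
        if gest < first_day:
            return None
        lo = onset + dt.timedelta(days=first_day)
        hi = min(onset + dt.timedelta(days=last_day), dd)
        return (lo, hi)

    return PregnancyEpisode(
        onset_date=onset,
        delivery_estimate=delivery,
        capped_294=capped,
        t1=window(0, T1_LAST_DAY),
        t2=window(T1_LAST_DAY + 1, T2_LAST_DAY),
        t3=window(T3_FIRST_DAY, MAX_GESTATION_DAYS),
    )


def assign_trimester(d: dt.date, episode: PregnancyEpisode) -> Trimester:
    if d < episode.onset_date:
        return Trimester.pre_pregnancy
    if d > episode.delivery_date:
        return Trimester.post_delivery
    offset = (d - episode.onset_date).days
    if offset <= T1_LAST_DAY:
        return Trimester.first
    if offset <= T2_LAST_DAY:
        return Trimester.second
    return Trimester.third


# ---------------------------------------------------------------------------
# Vectorised bulk path (one row per mother), used by the pipeline.

def estimate_onsets_frame(diagnoses: pd.DataFrame) -> pd.Series:
    """Per-person onset dates from a diagnoses table.

    Rows with a null ``ga_weeks`` are not GA-annotated and are ignored.
    Returns a Series indexed by person_id; persons without any annotated
    diagnosis are absent (undatable).
    """
    ga = diagnoses[diagnoses["ga_weeks"].notna()].copy()
    if ga.empty:
        return pd.Series(dtype="datetime64[ns]", name="onset_date")
    ga["ga_total"] = 7 * ga["ga_weeks"].astype(int) + ga["ga_days"].fillna(0).astype(int)
    # latest date wins; among ties the smallest implied gestation (later onset)
    ga = ga.sort_values(["person_id", "diagnosis_date", "ga_total"], ascending=[True, True, False])
    last = ga.groupby("person_id", sort=True).tail(1)
    onset = last["diagnosis_date"] - pd.to_timedelta(last["ga_total"], unit="D")
    onset.index = last["person_id"]
    onset.name = "onset_date"
    return onset


def estimate_deliveries_frame(
    delivery_entries: pd.DataFrame, birth_ym_by_mother: pd.Series
) -> pd.DataFrame:
    """Per-mother delivery estimates (vectorised three-tier rule).

    ``birth_ym_by_mother`` maps mother_id -> infant birth "YYYY-MM".
    Returns a frame indexed by mother_id with delivery_date and method.
    """
    out = pd.DataFrame(index=birth_ym_by_mother.index)
    out["delivery_date"] = pd.to_datetime(
        birth_ym_by_mother.values, format="%Y-%m"
    ) + pd.Timedelta(days=14)
    out["delivery_method"] = DeliveryMethod.month_midpoint.value

    if not delivery_entries.empty:
        ent = delivery_entries.merge(
            birth_ym_by_mother.rename("birth_ym"),
            left_on="person_id",
            right_index=True,
        ).copy()
        ent_ord = ent["entry_date"].dt.year * 12 + ent["entry_date"].dt.month
        birth_dt = pd.to_datetime(ent["birth_ym"], format="%Y-%m")
        birth_ord = birth_dt.dt.year * 12 + birth_dt.dt.month
        bad = (ent_ord - birth_ord).abs() > 1
        if bad.any():
            logger.warning("%d delivery entries outside birth month ±1 ignored", int(bad.sum()))
            ent = ent[~bad]
        for kind, method in (
            ("other_delivery_related", DeliveryMethod.other_entry),
            ("specific_procedure", DeliveryMethod.specific_entry),
        ):
            sub = ent[ent["entry_kind"] == kind]
            if sub.empty:
                continue
            latest = sub.groupby("person_id")["entry_date"].max()
            out.loc[latest.index, "delivery_date"] = latest
            out.loc[latest.index, "delivery_method"] = method.value
    return out


def build_episodes_frame(onsets: pd.Series, deliveries: pd.DataFrame) -> pd.DataFrame:
    """Episode table for all mothers that are datable on both ends.

    Columns: onset_date, delivery_date, delivery_method, capped_294,
    gestation_days; index mother_id.  Rows where onset exceeds delivery
    are dropped (undatable in practice; logged).
    """
    ep = deliveries.join(onsets, how="inner")
    ep = ep.dropna(subset=["onset_date"])
    bad = ep["onset_date"] > ep["delivery_date"]
    if bad.any():
        logger.warning("%d mothers with onset after delivery dropped", int(bad.sum()))
        ep = ep[~bad]
    span = (ep["delivery_date"] - ep["onset_date"]).dt.days
    ep["capped_294"] = span > MAX_GESTATION_DAYS
    ep.loc[ep["capped_294"], "onset_date"] = ep.loc[ep["capped_294"], "delivery_date"] - pd.Timedelta(
        days=MAX_GESTATION_DAYS
    )
    ep["gestation_days"] = (ep["delivery_date"] - ep["onset_date"]).dt.days
    ep.index.name = "mother_id"
    return ep[["onset_date", "delivery_date", "delivery_method", "capped_294", "gestation_days"]]


def episode_from_row(row: pd.Series) -> PregnancyEpisode:
    """Rebuild a :class:`PregnancyEpisode` from an episodes-frame row."""
    delivery = DeliveryEstimate(
        pd.Timestamp(row["delivery_date"]).date(), DeliveryMethod(row["delivery_method"])
    )
    return build_episode(pd.Timestamp(row["onset_date"]).date(), delivery)
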