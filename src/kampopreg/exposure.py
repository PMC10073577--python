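"""Drug exposure: date resolution, supply intervals, trimester flags, groups.

A prescription's exposure date is resolved through a fallback chain —
dispensing date, else admission date, else the 15th of the claim month —
and its exposure interval runs from that date for the days of supply.
A drug class is "exposed in trimester T" when any of its intervals
overlaps the trimester window (a configurable alternative classifies by
the resolved date alone).  Comparison groups: senna-glycoside exposure in
the first trimester excludes a mother outright; otherwise any
rhubarb-rhizome (KRR) exposure puts her in the KRR group even when MgO
was co-prescribed; MgO alone is the comparator group; neither leaves her
unexposed.
"""
from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from ._dates import month_mid
from .codelists import DrugDictionary
from .dating import PregnancyEpisode, Window

logger = logging.getLogger(__name__)

ExposureRule = Literal["overlap", "dispense_date"]


class DateProvenance(str, Enum):
    dispense = "dispense"
    admission = "admission"
    month_15th = "month_15th"


class Group(str, Enum):
    group1_mgo = "group1_mgo"
    group2_krr = "group2_krr"
    excluded_sg = "excluded_sg"
    unexposed = "unexposed"


@dataclass(frozen=True)
class ExposureInterval:
    drug_class: str
    product: str
    start_date: dt.date
    end_date: dt.date
    date_provenance: DateProvenance
    as_needed: bool

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError("interval end before start")


def resolve_exposure_date(
    dispense_date: Optional[dt.date],
    admission_date: Optional[dt.date],
    claim_year_month: str,
) -> tuple[dt.date, DateProvenance]:
    """Dispense date, else admission date, else the 15th of the claim month."""
    if dispense_date is not None and not pd.isna(dispense_date):
        return dispense_date, DateProvenance.dispense
    if admission_date is not None and not pd.isna(admission_date):
        return admission_date, DateProvenance.admission
    return month_mid(claim_year_month), DateProvenance.month_15th


def build_intervals(
    rxs: Iterable[dict], dictionary: DrugDictionary
) -> list[ExposureInterval]:
    """Classified supply intervals from prescription records (dicts with
    the prescriptions-table fields).  Unclassified codes are skipped;
    non-positive supplies rejected with a warning.  As-needed
    prescriptions are kept (they count as exposure in the primary
    analysis)."""
    out: list[ExposureInterval] = []
    for rx in rxs:
        cls = dictionary.classify(rx["drug_code"])
        if cls is None:
            continue
        supply = int(rx["days_of_supply"])
        if supply <= 0:
            logger.warning("prescription with days_of_supply=%d rejected", supply)
            continue
        start, prov = resolve_exposure_date(
            rx.get("dispense_date"), rx.get("admission_date"), rx["claim_year_month"]
        )
        if isinstance(start, pd.Timestamp):
            start = start.date()
        out.append(
            ExposureInterval(
                drug_class=cls,
                product=rx["drug_code"],
                start_date=start,
                end_date=start + dt.timedelta(days=supply - 1),
                date_provenance=prov,
                as_needed=bool(rx.get("as_needed", False)),
            )
        )
    return out


def _overlaps(interval: ExposureInterval, window: Window) -> bool:
    if window is None:
        return False
    lo, hi = window
    return interval.start_date <= hi and interval.end_date >= lo


def flag_trimester_exposure(
    intervals: Sequence[ExposureInterval],
    episode: PregnancyEpisode,
    rule: ExposureRule = "overlap",
) -> dict[str, dict[str, bool]]:
    """``flags[drug_class][trimester]`` by interval overlap (or, under the
    ``dispense_date`` rule, by the resolved start date alone)."""
    windows = {"t1": episode.t1, "t2": episode.t2, "t3": episode.t3}
    flags: dict[str, dict[str, bool]] = {}
    for iv in intervals:
        per = flags.setdefault(iv.drug_class, {t: False for t in windows})
        for t, win in windows.items():
            if win is None:
                continue
            if rule == "overlap":
                hit = _overlaps(iv, win)
            else:
                hit = win[0] <= iv.start_date <= win[1]
            per[t] = per[t] or hit
    return flags


def assign_group(first_trimester_flags: dict[str, bool]) -> Group:
    """Group from first-trimester class flags; senna overrides everything."""
    if first_trimester_flags.get("sg", False):
        return Group.excluded_sg
    if first_trimester_flags.get("krr", False):
        return Group.group2_krr
    if first_trimester_flags.get("mgo", False):
        return Group.group1_mgo
    return Group.unexposed


# ---------------------------------------------------------------------------
# Vectorised bulk path.

def build_intervals_frame(
    prescriptions: pd.DataFrame, dictionary: DrugDictionary
) -> pd.DataFrame:
    """One row per classified prescription with resolved dates.

    Columns: person_id, drug_class, product, start_date, end_date,
    date_provenance, as_needed.  Teratogen-listed codes are classified as
    drug_class='teratogen' so covariate derivation can reuse the interval
    machinery.
    """
    rx = prescriptions.copy()
    cmap = dictionary.class_map()
    cmap.update({c: "teratogen" for c in dictionary.teratogen_codes})
    rx["drug_class"] = rx["drug_code"].map(cmap)
    rx = rx[rx["drug_class"].notna()]
    bad = rx["days_of_supply"] <= 0
    if bad.any():
        logger.warning("%d prescriptions with non-positive supply rejected", int(bad.sum()))
        rx = rx[~bad]
    if rx.empty:
        return pd.DataFrame(
            columns=[
                "person_id",
                "drug_class",
                "product",
                "start_date",
                "end_date",
                "date_provenance",
                "as_needed",
            ]
        )
    month_15 = pd.to_datetime(rx["claim_year_month"], format="%Y-%m") + pd.Timedelta(days=14)
    start = rx["dispense_date"].fillna(rx["admission_date"]).fillna(month_15)
    prov = np.where(
        rx["dispense_date"].notna(),
        DateProvenance.dispense.value,
        np.where(
            rx["admission_date"].notna(),
            DateProvenance.admission.value,
            DateProvenance.month_15th.value,
        ),
    )
    out = pd.DataFrame(
        {
            "person_id": rx["person_id"].to_numpy(),
            "drug_class": rx["drug_class"].to_numpy(),
            "product": rx["drug_code"].to_numpy(),
            "start_date": pd.to_datetime(start).to_numpy(),
            "end_date": (
                pd.to_datetime(start)
                + pd.to_timedelta(rx["days_of_supply"].astype(int) - 1, unit="D")
            ).to_numpy(),
            "date_provenance": prov,
            "as_needed": rx["as_needed"].to_numpy(dtype=bool),
        }
    )
    return out


def flag_exposures_frame(
    intervals: pd.DataFrame,
    episodes: pd.DataFrame,
    rule: ExposureRule = "overlap",
) -> pd.DataFrame:
    """Per-mother exposure flags and groups, vectorised.

    Returns one row per mother in ``episodes`` with boolean columns
    ``{class}_{trimester}``, the supply-day totals
    ``{class}_t1_supply_days`` and all-as-needed indicators
    ``{class}_all_as_needed`` needed by the sensitivity analyses, plus
    the assigned ``group``.
    """
    classes = ("mgo", "krr", "sg", "daikenchuto", "teratogen")
    out = pd.DataFrame(index=episodes.index)
    iv = intervals.merge(
        episodes[["onset_date", "delivery_date", "gestation_days"]],
        left_on="person_id",
        right_index=True,
        how="inner",
    )
    for col in ("start_date", "end_date", "onset_date"):
        iv[col] = pd.to_datetime(iv[col])
    start_off = (iv["start_date"] - iv["onset_date"]).dt.days
    end_off = (iv["end_date"] - iv["onset_date"]).dt.days
    gest = iv["gestation_days"]
    bounds = {"t1": (0, 97), "t2": (98, 195), "t3": (196, None)}
    for t, (lo, hi) in bounds.items():
        win_lo = lo
        win_hi = np.minimum(hi, gest) if hi is not None else gest
        exists = gest >= win_lo
        if rule == "overlap":
            hit = exists & (start_off <= win_hi) & (end_off >= win_lo)
        else:
            hit = exists & (start_off >= win_lo) & (start_off <= win_hi)
        iv[f"hit_{t}"] = hit
    for cls in classes:
        sub = iv[iv["drug_class"] == cls]
        for t in ("t1", "t2", "t3"):
            col = f"{cls}_{t}"
            hits = sub.loc[sub[f"hit_{t}"], "person_id"].unique()
            out[col] = out.index.isin(hits)
        t1 = sub[sub["hit_t1"]]
        supply = (
            (t1["end_date"] - t1["start_date"]).dt.days + 1
        ).groupby(t1["person_id"]).sum()
        out[f"{cls}_t1_supply_days"] = (
            supply.reindex(out.index, fill_value=0).astype(int)
        )
        all_prn = t1.groupby("person_id")["as_needed"].all()
        out[f"{cls}_all_as_needed"] = (
            all_prn.reindex(out.index, fill_value=False).astype(bool)
        )
    out["group"] = np.select(
        [out["sg_t1"], out["krr_t1"], out["mgo_t1"]],
        [Group.excluded_sg.value, Group.group2_krr.value, Group.group1_mgo.value],
        default=Group.unexposed.value,
    )
    return out
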