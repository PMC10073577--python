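"""Infant outcome ascertainment: major congenital malformations (MCM).

An infant counts as having an MCM when at least one included ICD-10 code
(major subset of Q00-Q89, minus the configured minor-anomaly list) is
diagnosed within the first year of life.  Because births are recorded at
month granularity, "first year" is the first day of the birth month
through the last day of the eleventh month after it.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from ._dates import add_months, month_end, month_start
from .codelists import MCMCodeList, code_matches

FOLLOW_UP_MONTHS = 12


@dataclass(frozen=True)
class MCMOutcome:
    infant_id: str
    mcm_any: bool
    by_system: Mapping[str, bool]
    first_diagnosis_date: Optional[dt.date] = None

    def __post_init__(self) -> None:
        if self.mcm_any != any(self.by_system.values()):
            raise ValueError("mcm_any inconsistent with by_system")


def ascertain_mcm(
    infant_dx: pd.DataFrame, birth_year_month: str, codelist: MCMCodeList
) -> MCMOutcome:
    """Outcome for one infant from its diagnosis rows."""
    lo, hi = month_start(birth_year_month), month_end(
        add_months(birth_year_month, FOLLOW_UP_MONTHS - 1)
    )
    dx = infant_dx[
        (infant_dx["diagnosis_date"] >= pd.Timestamp(lo))
        & (infant_dx["diagnosis_date"] <= pd.Timestamp(hi))
    ]
    minor = code_matches(dx["icd10_code"], codelist.excluded_minor)
    dx = dx[~minor]
    by_system = {}
    first: Optional[pd.Timestamp] = None
    for system, prefixes in codelist.included.items():
        hits = dx[code_matches(dx["icd10_code"], prefixes)]
        by_system[system] = not hits.empty
        if not hits.empty:
            lead = hits["diagnosis_date"].min()
            first = lead if first is None else min(first, lead)
    infant_id = str(infant_dx["person_id"].iloc[0]) if len(infant_dx) else ""
    return MCMOutcome(
        infant_id=infant_id,
        mcm_any=any(by_system.values()),
        by_system=by_system,
        first_diagnosis_date=None if first is None else pd.Timestamp(first).date(),
    )


def ascertain_mcm_frame(
    diagnoses: pd.DataFrame,
    birth_ym_by_infant: pd.Series,
    codelist: MCMCodeList,
) -> pd.DataFrame:
    """Vectorised outcome table: one row per infant in ``birth_ym_by_infant``.

    Columns: mcm_any plus one boolean per organ system.
    """
    out = pd.DataFrame(index=birth_ym_by_infant.index)
    out.index.name = "infant_id"
    dx = diagnoses.merge(
        birth_ym_by_infant.rename("birth_ym"),
        left_on="person_id",
        right_index=True,
        how="inner",
    )
    if not dx.empty:
        birth_m = pd.to_datetime(
            dx["birth_ym"].to_numpy(), format="%Y-%m"
        ).to_numpy().astype("datetime64[M]")
        lo = birth_m.astype("datetime64[D]")
        hi = (birth_m + FOLLOW_UP_MONTHS).astype("datetime64[D]") - np.timedelta64(1, "D")
        in_window = (dx["diagnosis_date"].to_numpy() >= lo) & (
            dx["diagnosis_date"].to_numpy() <= hi
        )
        dx = dx[in_window & ~code_matches(dx["icd10_code"], codelist.excluded_minor)]
    for system, prefixes in codelist.included.items():
        if dx.empty:
            out[system] = False
            continue
        hits = dx.loc[code_matches(dx["icd10_code"], prefixes), "person_id"].unique()
        out[system] = out.index.isin(hits)
    out.insert(0, "mcm_any", out[list(codelist.included)].any(axis=1))
    return out


def tabulate_by_system(
    outcomes: pd.DataFrame, groups: pd.Series, codelist: MCMCodeList
) -> pd.DataFrame:
    """Prevalence table: counts and percentages per group and organ system.

    ``groups`` maps infant_id -> group label; only infants present there
    are tabulated.  The overall row counts infants with any MCM once,
    while an infant with malformations in several systems appears in each
    affected system's row.
    """
    rows = []
    joined = outcomes.join(groups.rename("group"), how="inner")
    for grp, sub in joined.groupby("group", sort=True):
        denom = len(sub)
        rows.append(
            {
                "group": grp,
                "system": "overall",
                "n": int(sub["mcm_any"].sum()),
                "denominator": denom,
                "pct": round(100 * sub["mcm_any"].mean(), 1) if denom else np.nan,
            }
        )
        for system in codelist.included:
            rows.append(
                {
                    "group": grp,
                    "system": system,
                    "n": int(sub[system].sum()),
                    "denominator": denom,
                    "pct": round(100 * sub[system].mean(), 1) if denom else np.nan,
                }
            )
    return pd.DataFrame(rows)
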