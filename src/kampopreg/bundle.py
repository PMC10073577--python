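"""The claims bundle: five tables plus mother-infant linkage.

This is the pipeline's sole input format.  Dialect: UTF-8 CSV, ISO-8601
dates (YYYY-MM-DD), year-months as YYYY-MM, empty string for missing,
booleans as ``true``/``false``.  Files: enrollment.csv, diagnoses.csv,
prescriptions.csv, delivery_entries.csv, links.csv (and truth.json when
the bundle is synthetic).
"""
from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

ENROLLMENT_COLS = [
    "person_id",
    "family_id",
    "role",
    "coverage_start_month",
    "coverage_end_month",
    "birth_year_month",
    "sex",
]
DIAGNOSES_COLS = ["person_id", "icd10_code", "diagnosis_date", "ga_weeks", "ga_days"]
PRESCRIPTIONS_COLS = [
    "person_id",
    "drug_code",
    "dispense_date",
    "admission_date",
    "claim_year_month",
    "days_of_supply",
    "as_needed",
]
DELIVERY_COLS = ["person_id", "entry_date", "entry_kind"]
LINKS_COLS = ["mother_id", "infant_id", "family_id"]

_FILES = {
    "enrollment": ENROLLMENT_COLS,
    "diagnoses": DIAGNOSES_COLS,
    "prescriptions": PRESCRIPTIONS_COLS,
    "delivery_entries": DELIVERY_COLS,
    "links": LINKS_COLS,
}
_DATE_COLS = {
    "diagnoses": ["diagnosis_date"],
    "prescriptions": ["dispense_date", "admission_date"],
    "delivery_entries": ["entry_date"],
}
_BOOL_COLS = {"prescriptions": ["as_needed"]}
_INT_COLS = {"diagnoses": ["ga_weeks", "ga_days"], "prescriptions": ["days_of_supply"]}


class BundleValidationError(ValueError):
    """The bundle violates a structural invariant; message lists rows."""


class BundleParseError(ValueError):
    """A CSV cell could not be parsed; message cites file and row index."""


@dataclass
class ClaimsBundle:
    enrollment: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    delivery_entries: pd.DataFrame
    links: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def validate(self) -> None:
        """Raise :class:`BundleValidationError` on any invariant violation."""
        problems: list[str] = []
        for name, cols in _FILES.items():
            df = self.tables()[name]
            missing = [c for c in cols if c not in df.columns]
            if missing:
                problems.append(f"{name}: missing columns {missing}")
        if not problems:
            infants = set(
                self.enrollment.loc[self.enrollment["role"] == "infant", "person_id"]
            )
            bad = self.links[~self.links["infant_id"].isin(infants)]
            for i in bad.index:
                problems.append(
                    f"links row {i}: infant {bad.loc[i, 'infant_id']} absent from "
                    "enrollment with role=infant"
                )
            rx = self.prescriptions
            no_ym = rx[rx["claim_year_month"].isna() | (rx["claim_year_month"] == "")]
            for i in no_ym.index:
                problems.append(f"prescriptions row {i}: claim_year_month missing")
            bad_supply = rx[rx["days_of_supply"] <= 0]
            for i in bad_supply.index:
                problems.append(
                    f"prescriptions row {i}: days_of_supply must be positive, got "
                    f"{rx.loc[i, 'days_of_supply']}"
                )
        if problems:
            raise BundleValidationError("; ".join(problems[:20]))

    def equals(self, other: "ClaimsBundle") -> bool:
        """Dialect-level equality: identical CSV serialisations."""
        mine, theirs = self.tables(), other.tables()
        return all(
            _format_for_csv(k, mine[k])[cols].to_csv(index=False, na_rep="")
            == _format_for_csv(k, theirs[k])[cols].to_csv(index=False, na_rep="")
            for k, cols in _FILES.items()
        )


def _format_for_csv(name: str, df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in _DATE_COLS.get(name, []):
        out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
    for c in _BOOL_COLS.get(name, []):
        out[c] = np.where(out[c], "true", "false")
    return out


def write_bundle(bundle: ClaimsBundle, directory: str | Path, truth=None) -> list[Path]:
    """Write the five CSVs (and truth.json when given); returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, cols in _FILES.items():
        path = directory / f"{name}.csv"
        _format_for_csv(name, bundle.tables()[name])[cols].to_csv(
            path, index=False, na_rep="", lineterminator="\n"
        )
        written.append(path)
    if truth is not None:
        path = directory / "truth.json"
        path.write_text(truth.to_json())
        written.append(path)
    return written


def _parse_dates(name: str, df: pd.DataFrame) -> pd.DataFrame:
    for c in _DATE_COLS.get(name, []):
        raw = df[c].astype("string")
        parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
        bad = raw.notna() & (raw != "") & parsed.isna()
        if bad.any():
            i = int(bad.idxmax())
            raise BundleParseError(
                f"{name}.csv row {i}: cannot parse {c}={raw[i]!r} as YYYY-MM-DD"
            )
        df[c] = parsed
    return df


def read_bundle(directory: str | Path) -> ClaimsBundle:
    """Read and validate a bundle directory.

    Missing files and malformed cells raise with the file (and row) named.
    """
    directory = Path(directory)
    frames: dict[str, pd.DataFrame] = {}
    for name, cols in _FILES.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"bundle file missing: {path.name} (in {directory})")
        df = pd.read_csv(path, dtype="string", keep_default_na=False)
        df = df.replace("", pd.NA)
        df = _parse_dates(name, df)
        for c in _INT_COLS.get(name, []):
            if c in df.columns:
                try:
                    df[c] = df[c].astype("Int64")
                except (TypeError, ValueError) as exc:
                    raise BundleParseError(f"{name}.csv: bad integer in {c}: {exc}") from exc
        for c in _BOOL_COLS.get(name, []):
            if c in df.columns:
                df[c] = df[c].fillna("false").str.lower().isin(["true", "1"])
        for c in cols:
            if c not in df.columns:
                df[c] = pd.Series(pd.NA, index=df.index, dtype="string")
        frames[name] = df[cols]
    if "days_of_supply" in frames["prescriptions"]:
        frames["prescriptions"]["days_of_supply"] = (
            frames["prescriptions"]["days_of_supply"].fillna(0).astype("int64")
        )
    bundle = ClaimsBundle(**frames)
    bundle.validate()
    return bundle
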