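"""Configurable code lists: drug dictionary, covariate and MCM ICD-10 lists.

All three lists ship as editable YAML defaults under ``kampopreg/data``.
ICD-10 codes are matched by prefix after stripping dots, so "Q65.3",
"Q653" and "Q65" interoperate.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

ORGAN_SYSTEMS = (
    "nervous",
    "eye_ear_face_neck",
    "circulatory",
    "respiratory",
    "cleft_lip_palate",
    "digestive",
    "genital",
    "urinary",
    "musculoskeletal",
    "other",
)


def _norm(code: str) -> str:
    return code.replace(".", "").upper().strip()


def code_matches(codes: pd.Series, prefixes: Iterable[str]) -> pd.Series:
    """Boolean mask: does each (dot-stripped) code start with any prefix?

    Matching is done once per distinct code, so repeated codes (the common
    case in claims) cost nothing extra.
    """
    pref = tuple(_norm(p) for p in prefixes)
    if not pref:
        return pd.Series(False, index=codes.index)
    uniq = pd.unique(codes.astype(str))
    hit = {u: u.replace(".", "").upper().startswith(pref) for u in uniq}
    return codes.astype(str).map(hit).fillna(False).astype(bool)


def _default_yaml(name: str) -> dict:
    with resources.files("kampopreg.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class DrugDictionary:
    """Maps raw drug codes to the four laxative classes plus teratogens."""

    mgo_codes: frozenset[str]
    sg_codes: frozenset[str]
    krr_products: frozenset[str]
    daikenchuto_codes: frozenset[str]
    teratogen_codes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        sets = [self.mgo_codes, self.sg_codes, self.krr_products, self.daikenchuto_codes]
        total = sum(len(s) for s in sets)
        if len(frozenset().union(*sets)) != total:
            raise ValueError("laxative code sets must be pairwise disjoint")

    def classify(self, code: str) -> str | None:
        """Drug class for a code: 'mgo' | 'krr' | 'sg' | 'daikenchuto' | None."""
        if code in self.mgo_codes:
            return "mgo"
        if code in self.krr_products:
            return "krr"
        if code in self.sg_codes:
            return "sg"
        if code in self.daikenchuto_codes:
            return "daikenchuto"
        return None

    def class_map(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for s, cls in (
            (self.mgo_codes, "mgo"),
            (self.krr_products, "krr"),
            (self.sg_codes, "sg"),
            (self.daikenchuto_codes, "daikenchuto"),
        ):
            out.update({c: cls for c in s})
        return out

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "DrugDictionary":
        raw = yaml.safe_load(Path(path).read_text()) if path else _default_yaml("drugs.yaml")
        return cls(
            mgo_codes=frozenset(raw["mgo_codes"]),
            sg_codes=frozenset(raw["sg_codes"]),
            krr_products=frozenset(raw["krr_products"]),
            daikenchuto_codes=frozenset(raw["daikenchuto_codes"]),
            teratogen_codes=frozenset(raw.get("teratogen_codes", [])),
        )


def default_drug_dictionary() -> DrugDictionary:
    return DrugDictionary.from_yaml()


@dataclass(frozen=True)
class CovariateCodeLists:
    """ICD-10 prefixes per maternal condition covariate."""

    prefixes: Mapping[str, tuple[str, ...]]

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "CovariateCodeLists":
        raw = yaml.safe_load(Path(path).read_text()) if path else _default_yaml("codelists.yaml")
        return cls(prefixes={k: tuple(v) for k, v in raw.items()})


def default_covariate_codelists() -> CovariateCodeLists:
    return CovariateCodeLists.from_yaml()


@dataclass(frozen=True)
class MCMCodeList:
    """Major-malformation ICD-10 prefixes per organ system, minus a minor list.

    Chromosomal abnormalities (Q90-Q99) are excluded at the cohort stage
    and are deliberately absent here.
    """

    included: Mapping[str, tuple[str, ...]]
    excluded_minor: tuple[str, ...] = ()
    chromosomal: tuple[str, ...] = tuple(f"Q9{i}" for i in range(10))

    def __post_init__(self) -> None:
        inc = {_norm(c) for v in self.included.values() for c in v}
        exc = {_norm(c) for c in self.excluded_minor}
        if inc & exc:
            raise ValueError(f"codes both included and excluded: {sorted(inc & exc)}")

    @property
    def systems(self) -> tuple[str, ...]:
        return tuple(self.included.keys())

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "MCMCodeList":
        raw = yaml.safe_load(Path(path).read_text()) if path else _default_yaml("mcm_codes.yaml")
        return cls(
            included={k: tuple(v) for k, v in raw["included"].items()},
            excluded_minor=tuple(raw.get("excluded_minor", [])),
        )


def default_mcm_codelist() -> MCMCodeList:
    return MCMCodeList.from_yaml()
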