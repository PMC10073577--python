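"""End-to-end analysis: claims bundle in, study tables out.

Stages: mother-infant linkage -> pregnancy dating -> eligibility cascade
-> exposure classification -> covariates -> outcome ascertainment ->
statistics.  ``run_pipeline`` returns everything in memory;
``write_report`` serialises the study tables, the per-mother
intermediate frames and the attrition report deterministically (same
bundle, byte-identical files).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .bundle import ClaimsBundle
from .codelists import (
    CovariateCodeLists,
    DrugDictionary,
    MCMCodeList,
    default_covariate_codelists,
    default_drug_dictionary,
    default_mcm_codelist,
)
from .cohort import (
    EligibilityReport,
    apply_eligibility,
    build_episodes_for_bundle,
    derive_covariates,
    link_mother_infant,
)
from .exposure import ExposureRule, Group, build_intervals_frame, flag_exposures_frame
from .outcomes import ascertain_mcm_frame, tabulate_by_system
from .stats import (
    LogisticModelResult,
    ORResult,
    SeparationError,
    analysis_or,
    compare_groups,
    prevalence_table,
    run_sensitivity,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    episodes: pd.DataFrame
    report: EligibilityReport
    rows: pd.DataFrame            # one row per retained mother-infant pair
    analysis_rows: pd.DataFrame   # the two comparison groups only
    exposure_flags: pd.DataFrame
    outcomes: pd.DataFrame
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    primary: Optional[tuple[ORResult, LogisticModelResult]] = None
    sensitivity: dict[int, tuple[ORResult, LogisticModelResult]] = field(default_factory=dict)

    def attrition(self) -> dict:
        out = self.report.to_dict()
        out["group_sizes"] = {
            k: int(v) for k, v in self.rows["group"].value_counts().sort_index().items()
        }
        return out


def run_pipeline(
    bundle: ClaimsBundle,
    drug_dictionary: DrugDictionary | None = None,
    covariate_codelists: CovariateCodeLists | None = None,
    mcm_codelist: MCMCodeList | None = None,
    exposure_rule: ExposureRule = "overlap",
    fit_models: bool = True,
    build_tables: bool = True,
) -> PipelineResult:
    """Run the full analysis on a claims bundle with the given code lists."""
    drug_dictionary = drug_dictionary or default_drug_dictionary()
    covariate_codelists = covariate_codelists or default_covariate_codelists()
    mcm_codelist = mcm_codelist or default_mcm_codelist()

    links = link_mother_infant(bundle)
    episodes = build_episodes_for_bundle(bundle, links)
    retained, report = apply_eligibility(bundle, episodes, links)

    ep_ret = episodes.loc[episodes.index.isin(retained["mother_id"])]
    intervals = build_intervals_frame(bundle.prescriptions, drug_dictionary)
    flags = flag_exposures_frame(intervals, ep_ret, rule=exposure_rule)
    covs = derive_covariates(bundle, retained, covariate_codelists, flags)

    birth_ym = retained.set_index("infant_id")["birth_year_month"]
    outcomes = ascertain_mcm_frame(bundle.diagnoses, birth_ym, mcm_codelist)

    rows = covs.merge(
        flags.add_prefix("").reset_index().rename(columns={"mother_id": "mother_id"}),
        on="mother_id",
        how="left",
    ).merge(
        outcomes.reset_index(), on="infant_id", how="left"
    )
    rows = rows[~rows["missing_age"]].reset_index(drop=True)
    rows["exposure_krr"] = rows["group"] == Group.group2_krr.value
    is_krr = rows["exposure_krr"].to_numpy()
    rows["index_supply_days_t1"] = np.where(
        is_krr, rows["krr_t1_supply_days"], rows["mgo_t1_supply_days"]
    )
    rows["index_all_as_needed"] = np.where(
        is_krr, rows["krr_all_as_needed"], rows["mgo_all_as_needed"]
    ).astype(bool)

    analysis_rows = rows[
        rows["group"].isin([Group.group1_mgo.value, Group.group2_krr.value])
    ].reset_index(drop=True)

    # --- study tables ----------------------------------------------------
    both_groups = analysis_rows["group"].nunique() == 2 and len(analysis_rows) > 0
    if build_tables:
        table1 = compare_groups(analysis_rows) if both_groups else pd.DataFrame()
        table2 = prevalence_table(
            intervals, ep_ret, krr_products=sorted(drug_dictionary.krr_products)
        )
        group_by_infant = analysis_rows.set_index("infant_id")["group"]
        table3 = tabulate_by_system(outcomes, group_by_infant, mcm_codelist)
    else:
        table1 = table2 = table3 = pd.DataFrame()

    primary = None
    sensitivity: dict[int, tuple[ORResult, LogisticModelResult]] = {}
    t4_rows = []
    if fit_models and both_groups:
        analyses: list[tuple[str, object]] = [("primary", None)] + [
            (f"sensitivity_{v}", v) for v in (1, 2, 3, 4)
        ]
        for label, variant in analyses:
            try:
                if variant is None:
                    crude, adjusted = analysis_or(analysis_rows)
                    primary = (crude, adjusted)
                else:
                    crude, adjusted = run_sensitivity(analysis_rows, variant)
                    sensitivity[variant] = (crude, adjusted)
            except (ValueError, SeparationError) as exc:
                logger.warning("%s analysis not estimable: %s", label, exc)
                t4_rows.append({"analysis": label, "n": np.nan, "n_events": np.nan})
                continue
            t4_rows.append(
                {
                    "analysis": label,
                    "n": crude.n,
                    "n_events": crude.n_events,
                    "crude_or": round(crude.or_point, 3),
                    "crude_ci_low": round(crude.ci_low, 3),
                    "crude_ci_high": round(crude.ci_high, 3),
                    "adjusted_or": round(adjusted.adjusted_or.or_point, 3),
                    "adjusted_ci_low": round(adjusted.adjusted_or.ci_low, 3),
                    "adjusted_ci_high": round(adjusted.adjusted_or.ci_high, 3),
                }
            )
    table4 = pd.DataFrame(t4_rows)

    return PipelineResult(
        episodes=episodes,
        report=report,
        rows=rows,
        analysis_rows=analysis_rows,
        exposure_flags=flags,
        outcomes=outcomes,
        table1=table1,
        table2=table2,
        table3=table3,
        table4=table4,
        primary=primary,
        sensitivity=sensitivity,
    )


def write_report(result: PipelineResult, directory: str | Path) -> list[Path]:
    """Write tables, intermediate frames and the attrition report as text."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    episodes = result.episodes.reset_index()
    for col in ("onset_date", "delivery_date"):
        episodes[col] = pd.to_datetime(episodes[col]).dt.strftime("%Y-%m-%d")
    frames = {
        "episodes.csv": episodes,
        "cohort.csv": result.rows,
        "exposure.csv": result.exposure_flags.reset_index(),
        "outcomes.csv": result.outcomes.reset_index(),
        "table1.csv": result.table1,
        "table2.csv": result.table2,
        "table3.csv": result.table3,
        "table4.csv": result.table4,
    }
    for name, df in frames.items():
        path = directory / name
        df.to_csv(path, index=False, na_rep="", lineterminator="\n")
        written.append(path)
    path = directory / "attrition.json"
    path.write_text(json.dumps(result.attrition(), indent=2, sort_keys=True) + "\n")
    written.append(path)
    return written
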