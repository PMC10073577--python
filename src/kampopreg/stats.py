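"""Statistical outputs: odds ratios, trend tests, group comparisons.

The primary contrast is KRR vs MgO first-trimester exposure and infant
malformation risk.  The crude odds ratio uses the Woolf (log-normal)
interval, ``exp(ln OR ± 1.96 * sqrt(1/a + 1/b + 1/c + 1/d))``; the
adjusted estimate comes from a maximum-likelihood logistic fit with a
Wald interval on the exposure term, covariates entered as categorical
bands for maternal age and delivery year plus binary flags for preterm
birth, epilepsy, diabetes, obesity and first-trimester teratogen use.
Prescription-frequency trends across trimesters use the Cochran-Armitage
test with scores 1, 2, 3; an exact conditional version (enumeration over
tables with fixed margins) backs the asymptotic one on small tables.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from itertools import product as iter_product
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

Z95 = 1.96

DEFAULT_ADJUSTMENT = (
    "maternal_age_band",
    "delivery_year_band",
    "preterm_birth",
    "epilepsy",
    "diabetes",
    "obesity",
    "teratogen_rx_t1",
)


class ZeroCellError(ValueError):
    """A 2x2 cell is zero; rerun with continuity=True to add 0.5 per cell."""


class SeparationError(ValueError):
    """The logistic model is perfectly separated; no finite MLE exists."""


class TrendDirection(str, Enum):
    increasing = "increasing"
    decreasing = "decreasing"
    none = "none"


@dataclass(frozen=True)
class TwoByTwo:
    """Counts: a/b exposed with/without outcome, c/d comparator with/without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @classmethod
    def from_rows(cls, exposed: pd.Series, outcome: pd.Series) -> "TwoByTwo":
        exposed = exposed.astype(bool)
        outcome = outcome.astype(bool)
        return cls(
            a=int((exposed & outcome).sum()),
            b=int((exposed & ~outcome).sum()),
            c=int((~exposed & outcome).sum()),
            d=int((~exposed & ~outcome).sum()),
        )


@dataclass(frozen=True)
class ORResult:
    or_point: float
    ci_low: float
    ci_high: float
    method: str
    n: int
    n_events: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_point <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")

    def rounded(self, ndigits: int = 3) -> tuple[float, float, float]:
        return (
            round(self.or_point, ndigits),
            round(self.ci_low, ndigits),
            round(self.ci_high, ndigits),
        )


@dataclass(frozen=True)
class TrendTestResult:
    z_statistic: float
    p_value: float
    direction: TrendDirection


@dataclass
class LogisticModelResult:
    coefficients: dict[str, tuple[float, float]]
    adjusted_or: ORResult
    converged: bool
    n: int
    dropped_terms: list[str] = field(default_factory=list)


def crude_or(t: TwoByTwo, continuity: bool = False) -> ORResult:
    """Woolf odds ratio with 95% CI for a 2x2 table."""
    a, b, c, d = (float(x) for x in (t.a, t.b, t.c, t.d))
    if continuity:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) == 0:
        raise ZeroCellError(
            "zero cell in 2x2 table; pass continuity=True for a 0.5 correction"
        )
    point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ORResult(
        or_point=point,
        ci_low=math.exp(math.log(point) - Z95 * se),
        ci_high=math.exp(math.log(point) + Z95 * se),
        method="woolf",
        n=t.a + t.b + t.c + t.d,
        n_events=t.a + t.c,
    )


def _design_matrix(
    rows: pd.DataFrame, exposure_col: str, covariate_cols: Sequence[str]
) -> tuple[pd.DataFrame, list[str]]:
    X = pd.DataFrame(index=rows.index)
    X[exposure_col] = rows[exposure_col].astype(float)
    for col in covariate_cols:
        s = rows[col]
        if isinstance(s.dtype, pd.CategoricalDtype):
            levels = [str(l) for l in s.cat.categories]
            levels = [l for l in levels if (s.astype(str) == l).any()]
        elif s.dtype == object or s.dtype.name == "string":
            levels = sorted(s.astype(str).unique())
        else:
            levels = None
        if levels is not None:
            for lvl in levels[1:]:  # first (youngest/earliest) level is reference
                X[f"{col}[{lvl}]"] = (s.astype(str) == lvl).astype(float)
        else:
            X[col] = s.astype(float)
    dropped = [c for c in X.columns if c != exposure_col and X[c].nunique() <= 1]
    if dropped:
        logger.warning("degenerate terms dropped from logistic model: %s", dropped)
        X = X.drop(columns=dropped)
    X = sm.add_constant(X, has_constant="add")
    return X, dropped


def fit_logistic(
    rows: pd.DataFrame,
    exposure_col: str = "exposure_krr",
    covariate_cols: Sequence[str] = DEFAULT_ADJUSTMENT,
    outcome_col: str = "mcm_any",
) -> LogisticModelResult:
    """ML logistic fit; Wald 95% CI on the exposure term.

    Constant covariate columns are dropped with a warning; perfect
    separation raises :class:`SeparationError`.
    """
    y = rows[outcome_col].astype(float)
    if y.nunique() < 2:
        raise ValueError("outcome has no variation; need >=1 event and >=1 non-event")
    X, dropped = _design_matrix(rows, exposure_col, covariate_cols)
    import warnings as _warnings

    fit = None
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", False))
        except (PerfectSeparationError, np.linalg.LinAlgError):
            converged = False
        if not converged:
            # Newton oscillates or hits a singular Hessian under
            # quasi-separation (e.g. a covariate stratum with no events);
            # BFGS is slower but stable there.
            try:
                fit = sm.Logit(y, X).fit(disp=0, maxiter=500, method="bfgs", gtol=1e-6)
                converged = bool(fit.mle_retvals.get("converged", False))
            except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
                if fit is None:
                    raise SeparationError(str(exc)) from exc
    coefs = {term: (float(fit.params[term]), float(fit.bse[term])) for term in X.columns}
    beta, se = coefs[exposure_col]
    if not (np.isfinite(beta) and np.isfinite(se)):
        raise SeparationError("non-finite exposure estimate (separation)")
    adj = ORResult(
        or_point=math.exp(beta),
        ci_low=math.exp(beta - Z95 * se),
        ci_high=math.exp(beta + Z95 * se),
        method="logistic_wald",
        n=len(rows),
        n_events=int(y.sum()),
    )
    return LogisticModelResult(
        coefficients=coefs, adjusted_or=adj, converged=converged, n=len(rows),
        dropped_terms=dropped,
    )


def _ca_statistic(r: np.ndarray, n: np.ndarray, s: np.ndarray) -> float:
    N, R = n.sum(), r.sum()
    return float(np.sum(s * (r - n * R / N)))


def cochran_armitage(
    counts: Sequence[int],
    denominators: Sequence[int],
    scores: Sequence[float] = (1, 2, 3),
    method: str = "asymptotic",
) -> TrendTestResult:
    """Cochran-Armitage trend test for a binary outcome over ordered groups.

    ``method='asymptotic'`` gives the usual normal-approximation z test;
    ``method='exact'`` enumerates all tables with the observed margins
    (multivariate hypergeometric null) and sums the probability of
    |T| >= |T_observed| — feasible for small counts only.
    """
    r = np.asarray(counts, dtype=float)
    n = np.asarray(denominators, dtype=float)
    s = np.asarray(scores, dtype=float)
    if len(r) != len(n) or len(r) != len(s):
        raise ValueError("counts, denominators and scores must have equal length")
    if (n <= 0).any():
        raise ValueError("zero denominator in trend test")
    if (r > n).any() or (r < 0).any():
        raise ValueError("counts must lie in [0, denominator]")
    N, R = n.sum(), r.sum()
    pbar = R / N
    T = _ca_statistic(r, n, s)
    var = pbar * (1 - pbar) * (np.sum(s**2 * n) - np.sum(s * n) ** 2 / N)
    if var <= 0:
        return TrendTestResult(0.0, 1.0, TrendDirection.none)
    z = T / math.sqrt(var)
    if method == "asymptotic":
        p = 2 * sps.norm.sf(abs(z))
    elif method == "exact":
        p = _ca_exact_p(r.astype(int), n.astype(int), s)
    else:
        raise ValueError(f"unknown method {method!r}")
    direction = TrendDirection.none
    if p < 0.05:
        direction = TrendDirection.increasing if z > 0 else TrendDirection.decreasing
    return TrendTestResult(float(z), float(min(p, 1.0)), direction)


def _ca_exact_p(r: np.ndarray, n: np.ndarray, s: np.ndarray) -> float:
    """Exact conditional two-sided p: enumerate tables with fixed margins."""
    R = int(r.sum())
    t_obs = abs(_ca_statistic(r.astype(float), n.astype(float), s))
    total = 0.0
    extreme = 0.0
    ranges = [range(0, int(ni) + 1) for ni in n[:-1]]
    for partial in iter_product(*ranges):
        last = R - sum(partial)
        if last < 0 or last > n[-1]:
            continue
        cand = np.array(list(partial) + [last], dtype=float)
        w = 1.0
        for ri, ni in zip(cand, n):
            w *= comb(int(ni), int(ri))
        total += w
        if abs(_ca_statistic(cand, n.astype(float), s)) >= t_obs - 1e-9:
            extreme += w
    return extreme / total


TABLE1_CATEGORICAL = (
    "maternal_age_band",
    "delivery_year_band",
    "hypertension",
    "diabetes",
    "obesity",
    "epilepsy",
    "phenylketonuria",
    "teratogen_rx_t1",
    "preterm_birth",
    "caesarean",
)


def compare_groups(
    rows: pd.DataFrame,
    group_col: str = "group",
    groups: tuple[str, str] = ("group1_mgo", "group2_krr"),
    categorical: Sequence[str] = TABLE1_CATEGORICAL,
    continuous: Sequence[str] = ("maternal_age_years",),
) -> pd.DataFrame:
    """Two-group characteristics table (chi-square / t-test p-values).

    Chi-square is Pearson without continuity correction; a variable with
    an expected cell below 1 is flagged unreliable.  Returns one row per
    variable level with per-group counts and percentages.
    """
    g1 = rows[rows[group_col] == groups[0]]
    g2 = rows[rows[group_col] == groups[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both comparison groups must be non-empty")
    out_rows = []
    for var in categorical:
        if var not in rows.columns:
            continue
        v1, v2 = g1[var], g2[var]
        levels = sorted(set(v1.astype(str)) | set(v2.astype(str)))
        table = np.array(
            [
                [(v1.astype(str) == lvl).sum() for lvl in levels],
                [(v2.astype(str) == lvl).sum() for lvl in levels],
            ]
        )
        informative = table.sum(axis=0) > 0
        table = table[:, informative]
        p = np.nan
        unreliable = False
        if table.shape[1] >= 2:
            chi2, p, _, expected = sps.chi2_contingency(table, correction=False)
            unreliable = bool((expected < 1).any())
        keep_levels = [lvl for lvl, k in zip(levels, informative) if k]
        for j, lvl in enumerate(keep_levels):
            out_rows.append(
                {
                    "variable": var,
                    "level": lvl,
                    "n_group1": int(table[0, j]),
                    "pct_group1": round(100 * table[0, j] / len(g1), 1),
                    "n_group2": int(table[1, j]),
                    "pct_group2": round(100 * table[1, j] / len(g2), 1),
                    "p_value": float(p) if np.isfinite(p) else np.nan,
                    "test": "chi2",
                    "unreliable": unreliable,
                }
            )
    for var in continuous:
        if var not in rows.columns:
            continue
        x1 = g1[var].dropna().astype(float)
        x2 = g2[var].dropna().astype(float)
        tt = sps.ttest_ind(x1, x2, equal_var=True)
        out_rows.append(
            {
                "variable": var,
                "level": "mean",
                "n_group1": round(float(x1.mean()), 2),
                "pct_group1": round(float(x1.std(ddof=1)), 2),
                "n_group2": round(float(x2.mean()), 2),
                "pct_group2": round(float(x2.std(ddof=1)), 2),
                "p_value": float(tt.pvalue),
                "test": "t",
                "unreliable": False,
            }
        )
    return pd.DataFrame(out_rows)


SENSITIVITY_LABELS = {
    1: "no teratogen prescription in the first trimester",
    2: "more than 30 supply days of the index laxative in the first trimester",
    3: "no combined MgO + KRR first-trimester exposure",
    4: "not exclusively as-needed prescriptions of the index laxative",
}


def _sensitivity_subset(rows: pd.DataFrame, variant: int) -> pd.DataFrame:
    if variant == 1:
        return rows[~rows["teratogen_rx_t1"].astype(bool)]
    if variant == 2:
        return rows[rows["index_supply_days_t1"] > 30]
    if variant == 3:
        return rows[~(rows["mgo_t1"].astype(bool) & rows["krr_t1"].astype(bool))]
    if variant == 4:
        return rows[~rows["index_all_as_needed"].astype(bool)]
    raise ValueError(f"unknown sensitivity variant {variant}")


def analysis_or(
    rows: pd.DataFrame,
    covariate_cols: Sequence[str] = DEFAULT_ADJUSTMENT,
) -> tuple[ORResult, LogisticModelResult]:
    """Crude and adjusted OR for the KRR-vs-MgO contrast on analysis rows."""
    t = TwoByTwo.from_rows(rows["exposure_krr"], rows["mcm_any"])
    return crude_or(t), fit_logistic(rows, covariate_cols=covariate_cols)


def run_sensitivity(
    rows: pd.DataFrame, variant: int, covariate_cols: Sequence[str] = DEFAULT_ADJUSTMENT
) -> tuple[ORResult, LogisticModelResult]:
    """One of the four sensitivity analyses: subset, then crude + adjusted OR."""
    sub = _sensitivity_subset(rows, variant)
    if sub.empty or sub["exposure_krr"].nunique() < 2:
        raise ValueError(
            f"sensitivity analysis {variant} ({SENSITIVITY_LABELS[variant]}): "
            "subset degenerate"
        )
    return analysis_or(sub, covariate_cols)


def prevalence_table(
    intervals: pd.DataFrame,
    episodes: pd.DataFrame,
    krr_products: Sequence[str] = (),
) -> pd.DataFrame:
    """Prescription-frequency table by class, product and trimester.

    Denominators: all datable mothers for the overall/first/second
    columns; only pregnancies reaching gestational day 196 for the third.
    Class-level rows carry a Cochran-Armitage trend p across trimesters.
    """
    n_all = len(episodes)
    n_t3 = int((episodes["gestation_days"] >= 196).sum())
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
    iv["hit_t1"] = (start_off <= np.minimum(97, gest)) & (end_off >= 0)
    iv["hit_t2"] = (gest >= 98) & (start_off <= np.minimum(195, gest)) & (end_off >= 98)
    iv["hit_t3"] = (gest >= 196) & (start_off <= gest) & (end_off >= 196)
    iv["hit_any"] = iv["hit_t1"] | iv["hit_t2"] | iv["hit_t3"]

    laxative_classes = ["mgo", "sg", "krr", "daikenchuto"]

    def one_row(label: str, sub: pd.DataFrame, with_trend: bool) -> dict:
        counts = {
            t: sub.loc[sub[f"hit_{t}"], "person_id"].nunique()
            for t in ("any", "t1", "t2", "t3")
        }
        row = {
            "item": label,
            "n_total": counts["any"],
            "pct_total": round(100 * counts["any"] / n_all, 2) if n_all else np.nan,
            "n_t1": counts["t1"],
            "pct_t1": round(100 * counts["t1"] / n_all, 2) if n_all else np.nan,
            "n_t2": counts["t2"],
            "pct_t2": round(100 * counts["t2"] / n_all, 2) if n_all else np.nan,
            "n_t3": counts["t3"],
            "pct_t3": round(100 * counts["t3"] / n_t3, 2) if n_t3 else np.nan,
            "trend_p": np.nan,
        }
        if with_trend and n_all and n_t3 and counts["t1"] + counts["t2"] + counts["t3"] > 0:
            res = cochran_armitage(
                [counts["t1"], counts["t2"], counts["t3"]], [n_all, n_all, n_t3]
            )
            row["trend_p"] = res.p_value
        return row

    lax = iv[iv["drug_class"].isin(laxative_classes)]
    rows = [one_row("all_laxatives", lax, True)]
    for cls in laxative_classes:
        rows.append(one_row(cls, iv[iv["drug_class"] == cls], True))
    for prod in krr_products:
        rows.append(one_row(prod, iv[iv["product"] == prod], False))
    return pd.DataFrame(rows)
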