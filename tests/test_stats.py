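import math

import numpy as np
import pandas as pd
import pytest

from kampopreg.stats import (
    DEFAULT_ADJUSTMENT,
    ORResult,
    SENSITIVITY_LABELS,
    TrendDirection,
    TwoByTwo,
    ZeroCellError,
    cochran_armitage,
    compare_groups,
    crude_or,
    fit_logistic,
    prevalence_table,
    run_sensitivity,
)


class TestCrudeOR:
    def test_study_two_by_two_reproduces_published_interval(self):
        """28/450 vs 680/9,852 events gives OR 0.895 (0.606-1.322)."""
        res = crude_or(TwoByTwo(a=28, b=422, c=680, d=9172))
        assert res.rounded() == (0.895, 0.606, 1.322)
        assert res.n == 10302 and res.n_events == 708

    def test_symmetric_table_gives_unity(self):
        assert crude_or(TwoByTwo(1, 1, 1, 1)).or_point == pytest.approx(1.0)

    def test_four_ninths(self):
        assert crude_or(TwoByTwo(10, 90, 20, 80)).or_point == pytest.approx(4 / 9)

    def test_zero_cell_raises_with_advice(self):
        with pytest.raises(ZeroCellError, match="continuity"):
            crude_or(TwoByTwo(0, 10, 5, 5))

    def test_continuity_correction_path(self):
        res = crude_or(TwoByTwo(0, 10, 5, 5), continuity=True)
        assert res.or_point == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))

    def test_inverting_exposure_reciprocates_or_and_swaps_ci(self):
        t = TwoByTwo(28, 422, 680, 9172)
        fwd = crude_or(t)
        rev = crude_or(TwoByTwo(t.c, t.d, t.a, t.b))
        assert rev.or_point == pytest.approx(1 / fwd.or_point)
        assert rev.ci_low == pytest.approx(1 / fwd.ci_high)
        assert rev.ci_high == pytest.approx(1 / fwd.ci_low)

    def test_ci_must_bracket_point(self):
        with pytest.raises(ValueError):
            ORResult(2.0, 2.5, 3.0, "woolf", 10, 5)


def _fixture_rows(a=12, b=88, c=40, d=360, rng_seed=0):
    """Analysis-row frame realising a given 2x2 with random covariates."""
    rng = np.random.default_rng(rng_seed)
    n = a + b + c + d
    exposed = np.r_[np.ones(a + b, bool), np.zeros(c + d, bool)]
    mcm = np.r_[np.ones(a, bool), np.zeros(b, bool), np.ones(c, bool), np.zeros(d, bool)]
    return pd.DataFrame(
        {
            "exposure_krr": exposed,
            "mcm_any": mcm,
            "maternal_age_band": pd.Categorical(
                rng.choice(["<=24", "25-29", "30-34", ">=35"], n),
                categories=["<=24", "25-29", "30-34", ">=35"], ordered=True,
            ),
            "delivery_year_band": pd.Categorical(
                rng.choice(["2010-2012", "2013-2015", "2016-2019"], n),
                categories=["2010-2012", "2013-2015", "2016-2019"], ordered=True,
            ),
            "preterm_birth": rng.random(n) < 0.12,
            "epilepsy": rng.random(n) < 0.01,
            "diabetes": rng.random(n) < 0.05,
            "obesity": rng.random(n) < 0.05,
            "teratogen_rx_t1": rng.random(n) < 0.01,
        }
    )


class TestLogistic:
    def test_exposure_only_model_equals_woolf(self):
        """Saturated 2x2 logistic: Wald CI == Woolf CI to 1e-6."""
        rows = _fixture_rows()
        woolf = crude_or(TwoByTwo.from_rows(rows["exposure_krr"], rows["mcm_any"]))
        fit = fit_logistic(rows, covariate_cols=())
        assert fit.adjusted_or.or_point == pytest.approx(woolf.or_point, abs=1e-6)
        assert fit.adjusted_or.ci_low == pytest.approx(woolf.ci_low, abs=1e-6)
        assert fit.adjusted_or.ci_high == pytest.approx(woolf.ci_high, abs=1e-6)

    def test_reference_levels_are_youngest_and_earliest(self):
        fit = fit_logistic(_fixture_rows())
        terms = set(fit.coefficients)
        assert "maternal_age_band[<=24]" not in terms
        assert "maternal_age_band[>=35]" in terms
        assert "delivery_year_band[2010-2012]" not in terms

    def test_constant_column_dropped_with_warning(self, caplog):
        rows = _fixture_rows()
        rows["epilepsy"] = False
        fit = fit_logistic(rows)
        assert any(t.startswith("epilepsy") for t in fit.dropped_terms)
        assert "epilepsy" not in fit.coefficients

    def test_no_outcome_variation_rejected(self):
        rows = _fixture_rows()
        rows["mcm_any"] = False
        with pytest.raises(ValueError, match="variation"):
            fit_logistic(rows)


class TestCochranArmitage:
    def test_flat_proportions_give_null_result(self):
        res = cochran_armitage([10, 10, 10], [100, 100, 100])
        assert res.z_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.direction is TrendDirection.none

    def test_published_all_laxatives_row_is_strongly_increasing(self):
        res = cochran_armitage(
            [11958, 17838, 19843], [75398, 75398, 75224]
        )
        assert res.p_value < 0.0001
        assert res.direction is TrendDirection.increasing

    def test_z_squared_matches_r_prop_trend_test(self):
        """Frozen reference: R's prop.trend.test chi-square statistics."""
        res = cochran_armitage([11958, 17838, 19843], [75398, 75398, 75224])
        assert res.z_statistic**2 == pytest.approx(2431.832695, abs=1e-4)
        small = cochran_armitage([3, 5, 9], [20, 20, 20])
        assert small.z_statistic**2 == pytest.approx(4.432285, abs=1e-5)
        assert small.p_value == pytest.approx(0.0352653, abs=1e-6)

    def test_exact_p_agrees_with_monte_carlo_permutation_oracle(self):
        """Exact conditional p vs a seeded permutation simulation."""
        counts, denoms = [1, 2, 3], [10, 10, 10]
        exact = cochran_armitage(counts, denoms, method="exact").p_value
        rng = np.random.default_rng(2024)
        n_subjects = np.repeat([0, 1, 2], denoms)
        events = sum(counts)
        scores = np.array([1.0, 2.0, 3.0])
        obs = abs(
            sum(
                s * (r - n * events / sum(denoms))
                for s, r, n in zip(scores, counts, denoms)
            )
        )
        hits = 0
        reps = 20000
        for _ in range(reps):
            chosen = rng.choice(n_subjects, size=events, replace=False)
            r = np.bincount(chosen, minlength=3)
            t = abs(
                sum(
                    s * (ri - n * events / sum(denoms))
                    for s, ri, n in zip(scores, r, denoms)
                )
            )
            if t >= obs - 1e-9:
                hits += 1
        mc = hits / reps
        se = math.sqrt(mc * (1 - mc) / reps)
        assert abs(exact - mc) <= 3 * se

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="denominator"):
            cochran_armitage([1, 2, 3], [10, 0, 10])

    def test_decreasing_trend_detected(self):
        res = cochran_armitage([30, 20, 5], [100, 100, 100])
        assert res.direction is TrendDirection.decreasing


class TestCompareGroups:
    def _rows_from_counts(self, n1, k1, n2, k2, var="preterm_birth"):
        df = pd.DataFrame(
            {
                "group": ["group1_mgo"] * n1 + ["group2_krr"] * n2,
                var: [True] * k1 + [False] * (n1 - k1) + [True] * k2 + [False] * (n2 - k2),
            }
        )
        return df

    def test_published_preterm_chi_square(self):
        """1,165/9,852 vs 72/450 preterm: uncorrected Pearson p = 0.0077."""
        rows = self._rows_from_counts(9852, 1165, 450, 72)
        table = compare_groups(rows, categorical=("preterm_birth",), continuous=())
        p = table["p_value"].iloc[0]
        assert p == pytest.approx(0.0077, abs=5e-5)

    def test_identical_groups_give_p_one(self):
        rows = self._rows_from_counts(200, 40, 200, 40)
        table = compare_groups(rows, categorical=("preterm_birth",), continuous=())
        assert table["p_value"].iloc[0] == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        rows = self._rows_from_counts(100, 10, 0, 0)
        with pytest.raises(ValueError, match="non-empty"):
            compare_groups(rows, categorical=("preterm_birth",), continuous=())

    def test_sparse_cells_flagged_unreliable(self):
        rows = self._rows_from_counts(50, 1, 4, 0)
        table = compare_groups(rows, categorical=("preterm_birth",), continuous=())
        assert table["unreliable"].all()

    def test_continuous_variable_uses_t_test(self):
        rng = np.random.default_rng(1)
        rows = pd.DataFrame(
            {
                "group": ["group1_mgo"] * 100 + ["group2_krr"] * 100,
                "maternal_age_years": np.r_[rng.normal(32, 4, 100), rng.normal(33, 4, 100)],
            }
        )
        table = compare_groups(rows, categorical=(), continuous=("maternal_age_years",))
        assert table["test"].iloc[0] == "t"
        assert 0 <= table["p_value"].iloc[0] <= 1


class TestSensitivity:
    def _rows(self):
        rows = _fixture_rows(a=10, b=90, c=30, d=370, rng_seed=3)
        rows["mgo_t1"] = ~rows["exposure_krr"]
        rows["krr_t1"] = rows["exposure_krr"]
        rng = np.random.default_rng(7)
        rows["index_supply_days_t1"] = rng.integers(7, 60, len(rows))
        rows["index_all_as_needed"] = rng.random(len(rows)) < 0.05
        return rows

    def test_exactly_30_days_excluded_31_included(self):
        rows = self._rows()
        rows["index_supply_days_t1"] = 30
        with pytest.raises(ValueError, match="degenerate"):
            run_sensitivity(rows, 2)
        rows["index_supply_days_t1"] = 31
        crude, _ = run_sensitivity(rows, 2)
        assert crude.n == len(rows)

    def test_variant_3_noop_without_dual_exposure(self):
        rows = self._rows()
        primary = crude_or(TwoByTwo.from_rows(rows["exposure_krr"], rows["mcm_any"]))
        crude, _ = run_sensitivity(rows, 3)
        assert crude.or_point == pytest.approx(primary.or_point)
        assert crude.n == primary.n

    def test_variant_1_drops_teratogen_exposed(self):
        rows = self._rows()
        rows["teratogen_rx_t1"] = False
        # mark 20 unexposed non-events so the remaining 2x2 stays non-degenerate
        rows.loc[rows.index[-20:], "teratogen_rx_t1"] = True
        crude, _ = run_sensitivity(rows, 1)
        assert crude.n == len(rows) - 20

    def test_variant_4_drops_prn_only_mothers(self):
        rows = self._rows()
        n_prn = int(rows["index_all_as_needed"].sum())
        assert n_prn > 0
        crude, _ = run_sensitivity(rows, 4)
        assert crude.n == len(rows) - n_prn

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            run_sensitivity(self._rows(), 5)


class TestPrevalenceTable:
    def test_five_mother_fixture_matches_recount(self):
        """Counts per trimester equal a brute-force per-mother recount."""
        onset = pd.Timestamp("2014-01-01")
        episodes = pd.DataFrame(
            {
                "onset_date": [onset] * 5,
                "delivery_date": [onset + pd.Timedelta(days=266)] * 5,
                "gestation_days": [266] * 5,
            },
            index=[f"M{i}" for i in range(5)],
        )
        episodes.index.name = "mother_id"

        def iv(m, cls, start_off, supply):
            start = onset + pd.Timedelta(days=start_off)
            return dict(
                person_id=m, drug_class=cls, product=cls,
                start_date=start, end_date=start + pd.Timedelta(days=supply - 1),
                date_provenance="dispense", as_needed=False,
            )

        intervals = pd.DataFrame(
            [
                iv("M0", "mgo", 10, 14),    # t1 only
                iv("M0", "mgo", 120, 14),   # t2 -> M0 counted once overall
                iv("M1", "mgo", 95, 10),    # straddles t1/t2
                iv("M2", "krr", 200, 7),    # t3 only
                iv("M3", "sg", -20, 10),    # before onset: no trimester
            ]
        )
        table = prevalence_table(intervals, episodes, krr_products=())
        mgo = table.set_index("item").loc["mgo"]
        assert (mgo["n_total"], mgo["n_t1"], mgo["n_t2"], mgo["n_t3"]) == (2, 2, 2, 0)
        krr = table.set_index("item").loc["krr"]
        assert (krr["n_total"], krr["n_t1"], krr["n_t3"]) == (1, 0, 1)
        sg = table.set_index("item").loc["sg"]
        assert sg["n_total"] == 0
        alll = table.set_index("item").loc["all_laxatives"]
        assert alll["n_total"] == 3  # M0, M1, M2

    def test_empty_prescriptions_give_zero_table(self):
        episodes = pd.DataFrame(
            {
                "onset_date": [pd.Timestamp("2014-01-01")],
                "delivery_date": [pd.Timestamp("2014-09-24")],
                "gestation_days": [266],
            },
            index=["M0"],
        )
        intervals = pd.DataFrame(
            columns=[
                "person_id", "drug_class", "product", "start_date", "end_date",
                "date_provenance", "as_needed",
            ]
        )
        table = prevalence_table(intervals, episodes)
        assert (table["n_total"] == 0).all()

    def test_third_trimester_denominator_restricted(self, calib_result):
        table2 = calib_result.table2
        retained = calib_result.episodes.loc[
            calib_result.episodes.index.isin(calib_result.rows["mother_id"])
        ]
        # the t3 percentage denominator is pregnancies reaching day 196
        mgo = table2.set_index("item").loc["mgo"]
        n_t3_denom = int((retained["gestation_days"] >= 196).sum())
        assert mgo["pct_t3"] == pytest.approx(100 * mgo["n_t3"] / n_t3_denom, abs=0.01)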