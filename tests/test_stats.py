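"""Statistical battery: gating, paired tests, ANOVA/ANCOVA, tabulation."""

import numpy as np
import pandas as pd
import pytest

from uvcoverage import stats as st


def _paired_frame(values, participants=None, region="face", **cols):
    """Long-format two-formulation frame from a (n, 2) array."""
    values = np.asarray(values)
    n = values.shape[0]
    participants = participants or [f"P{i:03d}" for i in range(n)]
    rows = []
    for i, pid in enumerate(participants):
        for j, form in enumerate(("sunscreen", "moisturiser")):
            row = {"participant": pid, "formulation": form, "region": region,
                   "percent_missed": values[i, j]}
            row.update({k: v[i] if np.ndim(v) else v for k, v in cols.items()})
            rows.append(row)
    return pd.DataFrame(rows)


class TestNormalityGate:
    def test_normal_samples_stay_parametric_at_test_level(self, rng):
        hits = sum(
            st.normality_gate(rng.normal(10, 2, 84)).path == "parametric"
            for _ in range(300)
        )
        assert 0.91 <= hits / 300 <= 0.99

    def test_lognormal_samples_choose_log_transform(self, rng):
        picks = [st.normality_gate(np.exp(rng.normal(1.0, 1.0, 84)))
                 for _ in range(100)]
        logged = sum(g.path == "transformed" and g.transform == "log"
                     for g in picks)
        assert logged > 50

    def test_constant_sample_routes_nonparametric_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            g = st.normality_gate(np.full(20, 3.0))
        assert g.path == "nonparametric"
        assert g.degenerate

    def test_transform_shift_makes_values_positive(self):
        g = st.GateResult(path="transformed", transform="log", shift=2.0)
        out = g.apply(np.array([-1.0, 0.0, 5.0]))
        assert np.isfinite(out).all()

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            st.normality_gate([1.0, 2.0])


class TestPairedCompare:
    def test_identical_samples_give_t0_p1(self):
        a = np.array([3.0, 4.0, 5.0, 6.0])
        res = st.paired_compare(a, a, gate=st.GateResult(path="parametric"))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_textbook_t_statistic(self):
        # differences [-1, 1, -1, -2]: mean -0.75, SD 1.2583, t = -1.192
        a = np.array([-1.0, 1.0, -1.0, -2.0])
        b = np.zeros(4)
        res = st.paired_compare(a, b, gate=st.GateResult(path="parametric"))
        assert res.test_name == "paired t-test"
        assert res.statistic == pytest.approx(-1.1921, abs=5e-4)
        assert res.df == 3

    def test_nonparametric_fallback_runs_mann_whitney(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
        res = st.paired_compare(a, b, gate=st.GateResult(path="nonparametric"))
        assert res.test_name == "mann-whitney U"
        assert res.assumption_path == "nonparametric"

    def test_wilcoxon_alternative_available(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
        res = st.paired_compare(a, b, gate=st.GateResult(path="nonparametric"),
                                nonparametric="wilcoxon")
        assert res.test_name == "wilcoxon signed-rank"

    def test_type_i_error_near_nominal_under_null(self, rng):
        n_rep, hits = 500, 0
        cov = np.array([[25.0, 12.5], [12.5, 25.0]])  # rho = 0.5
        gate = st.GateResult(path="parametric")
        for _ in range(n_rep):
            d = rng.multivariate_normal([10.0, 10.0], cov, size=84)
            hits += st.paired_compare(d[:, 0], d[:, 1], gate=gate).p_value < 0.05
        assert 0.03 <= hits / n_rep <= 0.07

    def test_length_mismatch_and_tiny_n(self):
        with pytest.raises(ValueError):
            st.paired_compare([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            st.paired_compare([1.0], [2.0])


class TestRmAnova:
    def test_f_equals_squared_paired_t(self, rng):
        vals = rng.normal([12.0, 16.0], [4.0, 5.0], size=(30, 2))
        table = _paired_frame(vals)
        res = st.rm_anova(table)
        t = st.paired_compare(vals[:, 0], vals[:, 1],
                              gate=st.GateResult(path="parametric"))
        assert res.statistic == pytest.approx(t.statistic ** 2, abs=1e-9)

    def test_all_equal_gives_f_zero(self):
        table = _paired_frame(np.full((10, 2), 7.0))
        res = st.rm_anova(table)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_statsmodels_anova_rm(self, rng):
        from statsmodels.stats.anova import AnovaRM

        n = 12
        rows = []
        for i in range(n):
            for j, level in enumerate(("a", "b", "c")):
                rows.append({"participant": f"P{i}", "formulation": level,
                             "region": "face",
                             "percent_missed": rng.normal(10 + 2 * j, 3)})
        table = pd.DataFrame(rows)
        res = st.rm_anova(table)
        oracle = AnovaRM(table, "percent_missed", "participant",
                         within=["formulation"]).fit()
        f_oracle = float(oracle.anova_table["F Value"].iloc[0])
        p_oracle = float(oracle.anova_table["Pr > F"].iloc[0])
        assert res.statistic == pytest.approx(f_oracle, rel=1e-9)
        assert res.p_value == pytest.approx(p_oracle, rel=1e-9)

    def test_missing_cell_lists_participant(self):
        table = _paired_frame(np.ones((5, 2)))
        table = table[~((table["participant"] == "P002")
                        & (table["formulation"] == "moisturiser"))]
        with pytest.raises(ValueError, match="P002"):
            st.rm_anova(table)


class TestSidakAndSubgroups:
    def test_sidak_closed_forms(self):
        assert st.sidak_adjust(0.02, 2) == pytest.approx(0.0396, abs=5e-5)
        assert st.sidak_alpha(0.05, 2) == pytest.approx(0.0253, abs=5e-5)

    def test_adjusted_p_at_least_raw_and_at_most_one(self, rng):
        for p in rng.random(50):
            for m in (1, 2, 5):
                adj = st.sidak_adjust(float(p), m)
                assert p <= adj <= 1.0

    def test_subgroup_contrasts_carry_adjustment(self, rng):
        vals = rng.normal([12.0, 16.0], [4.0, 5.0], size=(40, 2))
        sex = np.where(rng.random(40) < 0.5, "male", "female")
        table = _paired_frame(vals, sex=sex)
        out = st.subgroup_compare(table, "sex")
        assert out["anova"].p_value <= 1.0
        assert len(out["contrasts"]) == 2
        for c in out["contrasts"]:
            assert c.extras["p_adjusted"] >= c.p_value
            assert c.extras["m"] == 2

    def test_family_error_controlled_under_null(self, rng):
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            vals = rng.normal(12.0, 4.0, size=(40, 2))
            sex = np.r_[["male"] * 20, ["female"] * 20]
            out = st.subgroup_compare(_paired_frame(vals, sex=sex), "sex")
            rejections += any(c.extras["p_adjusted"] < 0.05
                              for c in out["contrasts"])
        assert rejections / n_rep <= 0.09

    def test_single_level_group_rejected(self):
        table = _paired_frame(np.ones((6, 2)), sex="female")
        with pytest.raises(ValueError):
            st.subgroup_compare(table, "sex")


class TestAncova:
    def _table(self, rng, n=60, slope=0.0):
        age = rng.uniform(18, 57, n)
        sex = np.where(rng.random(n) < 0.5, "male", "female")
        skin = np.where(rng.random(n) < 0.5, "I+II", "III+IV")
        y = slope * age + rng.normal(10, 2, n)
        return pd.DataFrame({
            "participant": [f"P{i}" for i in range(n)],
            "formulation": "sunscreen", "region": "face",
            "percent_missed": y, "age": age, "sex": sex, "skin_group": skin,
        })

    def test_covariate_slope_recovery(self, rng):
        res = st.ancova_two_factor(self._table(rng, slope=2.0))
        model = res["model"]
        lo, hi = model.conf_int().loc["age"]
        assert lo <= 2.0 <= hi
        assert res["slopes"]["age"] == pytest.approx(2.0, abs=3 * model.bse["age"])

    def test_reports_main_effects_interaction_and_covariate(self, rng):
        res = st.ancova_two_factor(self._table(rng))
        terms = [t for t in res if t not in ("slopes", "model")]
        assert any("sex" in t for t in terms)
        assert any("skin_group" in t for t in terms)
        assert any(":" in t for t in terms)  # interaction
        assert "age" in terms

    def test_aliased_factors_rejected(self, rng):
        table = self._table(rng)
        table["skin_group"] = np.where(table["sex"] == "male", "I+II", "III+IV")
        with pytest.raises(ValueError, match="rank"):
            st.ancova_two_factor(table)


class TestOrderEffect:
    def _table(self, rng, n_first=60, n_second=24, shift=0.0):
        n = n_first + n_second
        vals = rng.normal([12.0, 16.0], [4.0, 5.0], size=(n, 2))
        order = np.r_[["sunscreen_first"] * n_first,
                      ["moisturiser_first"] * n_second]
        vals[n_first:] += shift
        return _paired_frame(vals, order=order)

    def test_60_24_groups_run_cleanly(self, rng):
        out = st.order_effect_check(self._table(rng))
        assert set(out["formulation"]) == {"sunscreen", "moisturiser"}
        assert ((out["n_first"] == 60) | (out["n_first"] == 24)).all()
        assert (out["p_value"] <= 1.0).all()

    def test_single_member_group_errors(self, rng):
        out_table = self._table(rng, n_first=10, n_second=1)
        with pytest.raises(ValueError, match="n < 2"):
            st.order_effect_check(out_table)

    def test_missing_order_column(self, rng):
        with pytest.raises(ValueError, match="order"):
            st.order_effect_check(_paired_frame(np.ones((4, 2))))


class TestDoseResponse:
    def _records(self, slopes=(-0.2, -0.2), noise=0.0, rng=None):
        rows = []
        for form, slope in zip(("sunscreen", "moisturiser"), slopes):
            for pid in range(4):
                for mass in (50.0, 100.0, 250.0):
                    y = 180.0 + slope * mass
                    if rng is not None:
                        y += rng.normal(0, noise)
                    rows.append({"participant": f"P{pid}", "side": "left",
                                 "formulation": form, "mass": mass,
                                 "mean_intensity": y})
        return pd.DataFrame(rows)

    def test_exact_shared_line_gives_zero_formulation_effect(self):
        out = st.dose_response_regression(self._records())
        assert out["slopes"]["sunscreen"]["slope"] == pytest.approx(-0.2)
        assert out["slopes"]["moisturiser"]["slope"] == pytest.approx(-0.2)
        assert out["formulation_effect"].statistic == pytest.approx(0.0, abs=1e-8)

    def test_slope_recovery_with_noise(self, rng):
        out = st.dose_response_regression(
            self._records(slopes=(-0.2, -0.3), noise=1.0, rng=rng))
        for form, truth in (("sunscreen", -0.2), ("moisturiser", -0.3)):
            s = out["slopes"][form]
            assert abs(s["slope"] - truth) <= 3 * s["se"]
        assert out["formulation_effect"].p_value < 0.05

    def test_missing_formulation_errors(self):
        records = self._records()
        records = records[records["formulation"] == "sunscreen"]
        with pytest.raises(ValueError, match="formulation"):
            st.dose_response_regression(records)

    def test_single_mass_level_errors(self):
        records = self._records()
        records = records[records["mass"] == 100.0]
        with pytest.raises(ValueError, match="mass"):
            st.dose_response_regression(records)


class TestTabulateAndTable:
    def test_counts_and_percent(self):
        out = st.tabulate_binary(["missed"] * 66 + ["covered"] * 18)
        assert out["n_missed"] == 66 and out["n_total"] == 84
        assert out["percent_display"] == 78
        assert out["percent_missed"] == pytest.approx(78.571, abs=1e-3)

    @pytest.mark.parametrize("outcomes,percent", [
        (["covered"] * 10, 0), (["missed"] * 7, 100),
    ])
    def test_degenerate_tabulations(self, outcomes, percent):
        assert st.tabulate_binary(outcomes)["percent_display"] == percent

    def test_empty_or_bad_labels_rejected(self):
        with pytest.raises(ValueError):
            st.tabulate_binary([])
        with pytest.raises(ValueError, match="unrecognized"):
            st.tabulate_binary(["missed", "maybe"])

    def test_skin_type_collapse(self):
        df = pd.DataFrame({"skin_type": ["I", "II", "III", "IV"]})
        out = st.collapse_skin_type(df)
        assert list(out["skin_group"]) == ["I+II", "I+II", "III+IV", "III+IV"]

    def test_incomplete_pairing_detected(self):
        table = _paired_frame(np.ones((4, 2)))
        table = table[~((table["participant"] == "P001")
                        & (table["formulation"] == "sunscreen"))]
        with pytest.raises(ValueError, match="P001"):
            st.validate_study_table(table)
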