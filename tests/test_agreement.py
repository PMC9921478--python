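import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitstab import (bland_altman, holm_sidak, icc_a1, posthoc_vs_control,
                      rm_anova, rm_anova_with_posthoc)
from gaitstab.errors import (InsufficientDataError, ParameterError,
                             UndefinedICCError)


class TestBlandAltman:
    def test_identical_pairs(self):
        x = np.array([1.0, 2.0, 3.0])
        res = bland_altman(x, x)
        assert res.bias == 0.0
        assert res.loa_low == res.loa_high == 0.0

    def test_hand_computed_example(self):
        res = bland_altman([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.bias == pytest.approx(2.0)
        assert res.sd == pytest.approx(1.0)
        assert res.loa_low == pytest.approx(0.04)
        assert res.loa_high == pytest.approx(3.96)
        assert res.loa_width == pytest.approx(3.92)

    def test_per_subject_table(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=60)
        deg = ref - np.repeat([0.1, -0.2, 0.0], 20)
        res = bland_altman(ref, deg, subjects=np.repeat(list("abc"), 20))
        ps = res.per_subject.set_index("subject")
        assert ps.loc["a", "bias"] == pytest.approx(0.1, abs=1e-12)
        assert ps.loc["b", "bias"] == pytest.approx(-0.2, abs=1e-12)

    def test_insufficient_pairs(self):
        with pytest.raises(InsufficientDataError):
            bland_altman([1.0], [0.5])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=40),
           st.integers(0, 2**31 - 1))
    def test_limits_bracket_bias(self, ref, seed):
        deg = np.asarray(ref) + np.random.default_rng(seed).normal(
            size=len(ref))
        res = bland_altman(ref, deg)
        assert res.loa_low <= res.bias <= res.loa_high
        assert res.loa_low == pytest.approx(res.bias - 1.96 * res.sd)


def _icc_bruteforce(x):
    """Independent two-way mean-squares computation from raw sums."""
    n, k = x.shape
    grand = x.sum() / x.size
    msr = k * sum((x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum((x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
              for i in range(n) for j in range(k))
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestIccA1:
    def test_exact_copy_is_one(self):
        col = np.array([1.0, 2.0, 5.0, 3.0])
        res = icc_a1(np.column_stack([col, col]))
        assert res.icc == pytest.approx(1.0, abs=1e-12)
        assert res.band == "excellent"

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_oracle(self, seed):
        x = np.random.default_rng(seed).normal(size=(10, 2))
        assert icc_a1(x).icc == pytest.approx(_icc_bruteforce(x), abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        rows = rng.normal(0, 1, 30)
        x = np.column_stack([rows + rng.normal(0, 0.5, 30),
                             rows + 0.2 + rng.normal(0, 0.5, 30)])
        long = pd.DataFrame({
            "target": np.repeat(np.arange(30), 2),
            "rater": np.tile(["a", "b"], 30),
            "score": x.ravel()})
        table = pingouin.intraclass_corr(long, targets="target",
                                         raters="rater", ratings="score")
        table = table.set_index("Type")
        key = "ICC(A,1)" if "ICC(A,1)" in table.index else "ICC2"
        expected = float(table.loc[key, "ICC"])
        assert icc_a1(x).icc == pytest.approx(expected, abs=1e-8)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10_000, 2))
        assert abs(icc_a1(x).icc) < 0.05

    def test_band_thresholds_closed_lower_bounds(self):
        from gaitstab.agreement import ICCResult
        assert ICCResult(0.49, 1, 1, 1, 10, 2).band == "poor"
        assert ICCResult(0.50, 1, 1, 1, 10, 2).band == "moderate"
        assert ICCResult(0.75, 1, 1, 1, 10, 2).band == "good"
        assert ICCResult(0.90, 1, 1, 1, 10, 2).band == "excellent"

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedICCError):
            icc_a1(np.ones((5, 2)))

    def test_too_few_rows(self):
        with pytest.raises(InsufficientDataError):
            icc_a1(np.random.default_rng(0).normal(size=(2, 2)))


def _anova_bruteforce(x):
    s, c = x.shape
    grand = x.mean()
    ss_cond = s * sum((x[:, j].mean() - grand) ** 2 for j in range(c))
    ss_err = sum((x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
                 for i in range(s) for j in range(c))
    return (ss_cond / (c - 1)) / (ss_err / ((c - 1) * (s - 1)))


class TestRmAnova:
    def test_all_cells_equal(self):
        res = rm_anova(np.full((6, 4), 2.5))
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        x = np.random.default_rng(seed).normal(size=(10, 4))
        res = rm_anova(x)
        assert res.f_statistic == pytest.approx(_anova_bruteforce(x),
                                                abs=1e-10)
        assert (res.df_condition, res.df_error) == (3, 27)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        x = rng.normal(size=(12, 4)) + np.array([0.0, 0.3, -0.1, 0.5])
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 4),
            "cond": np.tile(list("wxyz"), 12),
            "val": x.ravel()})
        aov = pingouin.rm_anova(long, dv="val", within="cond",
                                subject="subject")
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        res = rm_anova(x)
        assert res.f_statistic == pytest.approx(float(aov["F"].iloc[0]),
                                                abs=1e-8)
        assert res.p_value == pytest.approx(float(aov[p_col].iloc[0]),
                                            abs=1e-10)

    def test_large_effect_tiny_p(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 0.05, size=(10, 4)) + np.array([0, 1, 2, 3.0])
        assert rm_anova(x).p_value < 1e-6

    def test_missing_cells_rejected(self):
        x = np.ones((4, 3))
        x[1, 2] = np.nan
        with pytest.raises(ParameterError):
            rm_anova(x)


class TestHolmSidak:
    def test_single_comparison_unchanged(self):
        assert holm_sidak([0.037]) == pytest.approx([0.037])

    def test_hand_evaluated_example(self):
        adj = holm_sidak([0.01, 0.02, 0.5])
        assert adj == pytest.approx([0.029701, 0.0396, 0.5], abs=1e-10)

    def test_all_ones(self):
        assert np.allclose(holm_sidak([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            holm_sidak([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    def test_adjusted_at_least_raw_and_monotone(self, raws):
        adj = holm_sidak(raws)
        assert np.all(adj >= np.asarray(raws) - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(raws, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestPosthoc:
    def test_control_referenced_table(self):
        rng = np.random.default_rng(11)
        table = pd.DataFrame({
            "normal": rng.normal(0, 0.1, 10),
            "eyes_closed": rng.normal(0, 0.1, 10),
            "wide": rng.normal(1.5, 0.1, 10),
            "tandem": rng.normal(-1.5, 0.1, 10)})
        res = rm_anova_with_posthoc(table, control="normal")
        ph = res.posthoc.set_index("condition")
        assert set(ph.index) == {"eyes_closed", "wide", "tandem"}
        assert np.all(ph["p_adj"] >= ph["p_raw"] - 1e-15)
        assert bool(ph.loc["wide", "significant"])
        assert bool(ph.loc["tandem", "significant"])
        assert not bool(ph.loc["eyes_closed", "significant"])

    def test_missing_control_rejected(self):
        with pytest.raises(ParameterError):
            posthoc_vs_control(pd.DataFrame({"a": [1, 2], "b": [2, 3]}),
                               control="normal")
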