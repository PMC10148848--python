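"""Composites, correlation machinery, Meng z, mixed ANOVA, post-hocs."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from patchforage import (
    composite_scores,
    correlation_matrix,
    meng_z_test,
    mixed_anova,
    normality_screen,
    posthoc_tests,
)

DELAYS = [0.0, 6.0, 12.0, 18.0, 24.0]


def tidy_metrics(values: dict[str, list[float]], sexes: dict[str, str],
                 col: str = "pc") -> pd.DataFrame:
    rows = []
    for rat, vals in values.items():
        for d, v in zip(DELAYS, vals):
            row = {"rat_id": rat, "sex": sexes[rat], "cod_s": d,
                   "pc": 1.0, "tip_s": 1.0, "wr_ul_min_kg": 1.0,
                   "vd_pct": 1.0, "td_pct": (np.nan if d == 0 else 1.0)}
            row[col] = v
            if col == "td_pct" and d == 0:
                row[col] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


class TestCompositeScores:
    def test_sums_across_delays(self):
        metrics = tidy_metrics({"a": [10, 8, 6, 4, 2]}, {"a": "male"}, col="pc")
        fits = pd.DataFrame({"rat_id": ["a"], "k": [0.1], "b": [0.8], "auc": [0.5]})
        scores = composite_scores(metrics, fits)
        assert scores.loc[0, "pc"] == 30.0
        assert scores.loc[0, "k"] == 0.1 and scores.loc[0, "auc"] == 0.5
        # td sums its four defined delays of 1.0 each
        assert scores.loc[0, "td"] == 4.0

    def test_rat_with_missing_cell_is_excluded(self):
        metrics = tidy_metrics({"a": [1, 1, 1, 1, 1], "b": [1, np.nan, 1, 1, 1]},
                               {"a": "male", "b": "male"}, col="wr_ul_min_kg")
        fits = pd.DataFrame({"rat_id": ["a", "b"], "k": [0.1, 0.1],
                             "b": [0.8, 0.8], "auc": [0.5, 0.5]})
        scores = composite_scores(metrics, fits)
        assert list(scores["rat_id"]) == ["a"]


class TestCorrelationMatrix:
    @staticmethod
    def scores_frame(n=20, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=n)
        return pd.DataFrame({
            "rat_id": [f"r{i}" for i in range(n)], "sex": ["male"] * n,
            "k": base + rng.normal(0, 0.5, n), "auc": -base + rng.normal(0, 0.5, n),
            "vd": base.copy(), "td": base.copy(),
            "tip": rng.normal(size=n), "pc": rng.normal(size=n),
            "wr": rng.normal(size=n),
        })

    def test_identical_columns_correlate_perfectly(self):
        mat = correlation_matrix(self.scores_frame(), "male")
        assert mat.loc["vd", "td"] == pytest.approx(1.0)
        assert (np.diag(mat) == 1.0).all()
        assert np.allclose(mat, mat.T, equal_nan=True)

    def test_zero_variance_variable_goes_missing(self):
        df = self.scores_frame()
        df["wr"] = 3.0
        mat = correlation_matrix(df, "male")
        assert mat.loc["wr", "k"] != mat.loc["wr", "k"]  # NaN
        assert mat.loc["wr", "wr"] == 1.0

    def test_small_cohorts_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            correlation_matrix(self.scores_frame(n=3), "male")

    def test_known_latent_correlation_is_recovered(self):
        rng = np.random.default_rng(7)
        n = 500
        shared = rng.standard_normal(n)
        df = self.scores_frame(n)
        df["tip"] = shared
        df["td"] = 0.8 * shared + math.sqrt(1 - 0.64) * rng.standard_normal(n)
        mat = correlation_matrix(df, "male")
        assert mat.loc["tip", "td"] == pytest.approx(0.8, abs=0.05)


def meng_reference(r_jx, r_jy, r_xy, n):
    """Independent re-derivation of the published overlapping-correlation z."""
    z1 = 0.5 * math.log((1 + r_jx) / (1 - r_jx))
    z2 = 0.5 * math.log((1 + r_jy) / (1 - r_jy))
    r2 = (r_jx * r_jx + r_jy * r_jy) / 2.0
    f = (1.0 - r_xy) / (2.0 * (1.0 - r2))
    f = 1.0 if f > 1.0 else f
    h = (1.0 - f * r2) / (1.0 - r2)
    return (z1 - z2) * math.sqrt((n - 3.0) / (2.0 * (1.0 - r_xy) * h))


class TestMengZ:
    def test_equal_correlations_give_zero_z_unit_p(self):
        c = meng_z_test(0.4, 0.4, 0.2, 50)
        assert c.z == 0.0 and c.p == pytest.approx(1.0)

    @given(
        r_jx=st.floats(-0.95, 0.95), r_jy=st.floats(-0.95, 0.95),
        r_xy=st.floats(-0.9, 0.9), n=st.integers(5, 5000),
    )
    def test_antisymmetric_under_swap(self, r_jx, r_jy, r_xy, n):
        a = meng_z_test(r_jx, r_jy, r_xy, n)
        b = meng_z_test(r_jy, r_jx, r_xy, n)
        assert a.z == pytest.approx(-b.z, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    @pytest.mark.parametrize("r_jx", [-0.8, -0.3, 0.0, 0.3, 0.87])
    @pytest.mark.parametrize("r_jy", [-0.30, 0.2, 0.6])
    @pytest.mark.parametrize("r_xy", [-0.4, 0.0, 0.5])
    @pytest.mark.parametrize("n", [10, 100, 896])
    def test_matches_independent_reference_formula(self, r_jx, r_jy, r_xy, n):
        assert meng_z_test(r_jx, r_jy, r_xy, n).z == pytest.approx(
            meng_reference(r_jx, r_jy, r_xy, n), abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            meng_z_test(1.0, 0.5, 0.2, 50)
        with pytest.raises(ValueError):
            meng_z_test(0.5, 0.4, 0.2, 3)


def manual_mixed_ss(df: pd.DataFrame, dv: str):
    """Classical sums-of-squares decomposition for the balanced two-way
    mixed design (between: sex, within: delay), written from the textbook
    formulas independently of any library."""
    grand = df[dv].mean()
    subjects = df.groupby("rat_id")[dv].mean()
    sex_of = df.groupby("rat_id")["sex"].first()
    a = df["cod_s"].nunique()  # within levels
    ss_between_subj = a * ((subjects - grand) ** 2).sum()
    sex_means = df.groupby("sex")[dv].mean()
    n_per_sex = sex_of.value_counts()
    ss_sex = a * sum(n_per_sex[s] * (sex_means[s] - grand) ** 2 for s in sex_means.index)
    ss_subj_within = ss_between_subj - ss_sex
    delay_means = df.groupby("cod_s")[dv].mean()
    n_subj = df["rat_id"].nunique()
    ss_delay = n_subj * ((delay_means - grand) ** 2).sum()
    cell = df.groupby(["sex", "cod_s"])[dv].mean()
    ss_cells = sum(n_per_sex[s] * (cell[s, d] - grand) ** 2 for s, d in cell.index)
    ss_inter = ss_cells - ss_sex - ss_delay
    ss_total = ((df[dv] - grand) ** 2).sum()
    ss_err_within = ss_total - ss_between_subj - ss_delay - ss_inter
    return dict(sex=ss_sex, delay=ss_delay, inter=ss_inter,
                subj=ss_subj_within, err=ss_err_within, total=ss_total)


class TestMixedAnova:
    @staticmethod
    def fixture_frame(n_per_sex=4, seed=5, sex_shift=2.0, delay_slope=0.5):
        rng = np.random.default_rng(seed)
        rows = []
        for sex, shift in [("male", 0.0), ("female", sex_shift)]:
            for i in range(n_per_sex):
                rid = f"{sex[0]}{i}"
                subj = rng.normal(0, 1.0)
                for d in DELAYS:
                    rows.append({"rat_id": rid, "sex": sex, "cod_s": d,
                                 "y": shift + subj + delay_slope * d + rng.normal(0, 0.5)})
        return pd.DataFrame(rows)

    def test_f_and_partial_eta_match_manual_decomposition(self):
        df = self.fixture_frame()
        table = mixed_anova(df, "y").set_index("Source")
        ss = manual_mixed_ss(df, "y")
        n_subj, a = 8, 5
        df_sex, df_subj = 1, n_subj - 2
        df_delay, df_err = a - 1, (n_subj - 2) * (a - 1)
        f_sex = (ss["sex"] / df_sex) / (ss["subj"] / df_subj)
        f_delay = (ss["delay"] / df_delay) / (ss["err"] / df_err)
        f_inter = (ss["inter"] / df_delay) / (ss["err"] / df_err)
        assert table.loc["sex", "F"] == pytest.approx(f_sex, rel=1e-6)
        assert table.loc["cod_s", "F"] == pytest.approx(f_delay, rel=1e-6)
        assert table.loc["Interaction", "F"] == pytest.approx(f_inter, rel=1e-6)
        assert table.loc["sex", "np2"] == pytest.approx(
            ss["sex"] / (ss["sex"] + ss["subj"]), rel=1e-6)
        assert table.loc["cod_s", "np2"] == pytest.approx(
            ss["delay"] / (ss["delay"] + ss["err"]), rel=1e-6)

    def test_sums_of_squares_are_additive(self):
        ss = manual_mixed_ss(self.fixture_frame(seed=11), "y")
        assert ss["sex"] + ss["subj"] + ss["delay"] + ss["inter"] + ss["err"] == pytest.approx(
            ss["total"], rel=1e-9)

    def test_pure_sex_shift_loads_on_sex_not_delay(self):
        df = self.fixture_frame(n_per_sex=30, seed=2, sex_shift=5.0, delay_slope=0.0)
        table = mixed_anova(df, "y").set_index("Source")
        assert table.loc["sex", "F"] > 50
        assert table.loc["cod_s", "F"] < 3


class TestPosthoc:
    @staticmethod
    def frame(male_mean=0.0, female_mean=0.0, seed=3, n=10, sd=1.0):
        rng = np.random.default_rng(seed)
        rows = []
        for sex, mu in [("male", male_mean), ("female", female_mean)]:
            for i in range(n):
                for d in DELAYS:
                    rows.append({"rat_id": f"{sex[0]}{i}", "sex": sex, "cod_s": d,
                                 "y": rng.normal(mu, sd)})
        return pd.DataFrame(rows)

    def test_identical_groups_give_zero_t_and_d(self):
        df = self.frame()
        df["y"] = df.groupby("cod_s")["y"].transform(lambda s: 1.0)
        out = posthoc_tests(df, "y")["between"]
        assert (out["t"].fillna(0) == 0).all()
        # zero pooled SD: d flagged undefined
        assert out["d"].isna().all()

    def test_t_and_d_match_hand_formulas(self):
        df = self.frame(male_mean=1.0, seed=9)
        out = posthoc_tests(df, "y")["between"].set_index("cod_s")
        d0 = df[df["cod_s"] == 0.0]
        m = d0.loc[d0["sex"] == "male", "y"].to_numpy()
        f = d0.loc[d0["sex"] == "female", "y"].to_numpy()
        sp2 = ((len(m) - 1) * m.var(ddof=1) + (len(f) - 1) * f.var(ddof=1)) / (len(m) + len(f) - 2)
        t_hand = (m.mean() - f.mean()) / math.sqrt(sp2 * (1 / len(m) + 1 / len(f)))
        assert out.loc[0.0, "t"] == pytest.approx(t_hand, rel=1e-9)
        assert out.loc[0.0, "d"] == pytest.approx((m.mean() - f.mean()) / math.sqrt(sp2), rel=1e-9)
        assert out.loc[0.0, "alpha_bonf"] == pytest.approx(0.05 / 5)

    def test_within_family_is_all_delay_pairs(self):
        out = posthoc_tests(self.frame(), "y")["within"]
        assert len(out) == 10
        assert (out["p_bonf"] >= out["p"] - 1e-15).all()


class TestNormalityScreen:
    def test_symmetric_sample_passes(self):
        x = np.concatenate([np.linspace(-1, 1, 101)])
        skew, ok = normality_screen(x)
        assert skew == pytest.approx(0.0, abs=1e-12) and ok

    def test_exponential_sample_fails_with_skewness_near_two(self):
        rng = np.random.default_rng(0)
        skew, ok = normality_screen(rng.exponential(size=10_000))
        assert skew == pytest.approx(2.0, abs=0.25) and not ok

    def test_constant_sample_is_flagged_undefined(self):
        skew, ok = normality_screen([2.0, 2.0, 2.0])
        assert math.isnan(skew) and not ok
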