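"""The repeated-measures agreement battery against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from mocapval.agreement import (
    AgreementModel,
    icc21,
    icc_nested_bootstrap,
    loa_repeated,
    loa_through_range,
    rmc,
    rmse_mixed,
)


# --- independent ANOVA oracle ----------------------------------------------


def icc21_anova_oracle(matrix, form):
    """Textbook two-way ANOVA ICC(2,1), coded with explicit loops."""
    x = np.asarray(matrix, float)
    n, k = x.shape
    grand = x.mean()
    msr = k * sum((x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    if form == "consistency":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


FIXED_MATRIX = np.array([
    [9.0, 2.0],
    [6.0, 1.0],
    [8.0, 4.0],
    [7.0, 1.0],
    [10.0, 5.0],
    [6.0, 2.0],
])


class TestLoaRepeated:
    def test_one_pair_per_subject_reduces_to_classic(self):
        rng = np.random.default_rng(1)
        d = rng.normal(2.0, 3.0, 30)
        subjects = np.arange(30)
        lo, md, hi = loa_repeated(d, subjects)
        assert md == pytest.approx(d.mean())
        assert hi - md == pytest.approx(1.96 * d.std(ddof=1), abs=1e-12)

    def test_constant_difference_collapses(self):
        d = np.full(12, 3.5)
        subjects = np.repeat(np.arange(4), 3)
        assert loa_repeated(d, subjects) == pytest.approx((3.5, 3.5, 3.5))

    def test_variance_components_recovered(self):
        # sigma_between = 3, sigma_within = 4 -> total SD 5
        rng = np.random.default_rng(2)
        n_subj, n_rep = 50, 10
        d = (np.repeat(rng.normal(0, 3.0, n_subj), n_rep)
             + rng.normal(0, 4.0, n_subj * n_rep))
        subjects = np.repeat(np.arange(n_subj), n_rep)
        lo, md, hi = loa_repeated(d, subjects)
        assert (hi - lo) / 2 == pytest.approx(1.96 * 5.0, rel=0.05)

    def test_single_subject_warns(self):
        with pytest.warns(UserWarning, match="single subject"):
            loa_repeated(np.array([1.0, 2.0, 3.0]), np.zeros(3))

    def test_swapping_systems_mirrors_limits(self):
        rng = np.random.default_rng(3)
        d = rng.normal(1.0, 2.0, 40)
        subjects = np.repeat(np.arange(10), 4)
        lo, md, hi = loa_repeated(d, subjects)
        lo2, md2, hi2 = loa_repeated(-d, subjects)
        assert (lo2, md2, hi2) == pytest.approx((-hi, -md, -lo))


class TestIcc21:
    def test_identical_columns_give_one(self):
        x = np.column_stack([FIXED_MATRIX[:, 0], FIXED_MATRIX[:, 0]])
        assert icc21(x, "agreement") == pytest.approx(1.0)
        assert icc21(x, "consistency") == pytest.approx(1.0)

    def test_constant_offset_hurts_agreement_not_consistency(self):
        x = np.column_stack([FIXED_MATRIX[:, 0], FIXED_MATRIX[:, 0] + 5.0])
        assert icc21(x, "consistency") == pytest.approx(1.0)
        assert icc21(x, "agreement") < 1.0

    @pytest.mark.parametrize("form", ["agreement", "consistency"])
    def test_fixed_matrix_matches_anova_oracle(self, form):
        assert icc21(FIXED_MATRIX, form) == pytest.approx(
            icc21_anova_oracle(FIXED_MATRIX, form), abs=1e-12
        )

    @pytest.mark.parametrize("form", ["agreement", "consistency"])
    def test_random_matrices_match_oracle(self, form):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.normal(0, 1, size=(rng.integers(3, 12), 2))
            assert icc21(x, form) == pytest.approx(
                icc21_anova_oracle(x, form), abs=1e-12
            )

    def test_agreement_never_exceeds_consistency_when_msc_large(self):
        # a systematic column offset inflates MSC; whenever the numerator is
        # positive the larger agreement denominator can only shrink the ICC
        rng = np.random.default_rng(5)
        checked = 0
        for _ in range(80):
            x = rng.normal(0, 1, size=(8, 2))
            x[:, 0] = 0.7 * x[:, 0] + 0.7 * x[:, 1]  # correlated raters
            x[:, 1] += rng.uniform(0.5, 2.0)  # systematic column offset
            n, k = x.shape
            grand = x.mean()
            msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
            sse = ((x - x.mean(1, keepdims=True) - x.mean(0) + grand) ** 2).sum()
            mse = sse / ((n - 1) * (k - 1))
            if msc < mse:
                continue
            checked += 1
            assert icc21(x, "agreement") <= icc21(x, "consistency") + 1e-12
        assert checked > 40

    def test_cross_check_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        x = rng.normal(50, 10, size=(10, 2)) + rng.normal(0, 3, size=(10, 2))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(10), 2),
            "rater": np.tile(["A", "B"], 10),
            "score": x.ravel(),
        })
        res = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                       ratings="score").set_index("Type")
        agr = res.loc[res.index.intersection(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0]
        cons = res.loc[res.index.intersection(["ICC3", "ICC(C,1)"]), "ICC"].iloc[0]
        assert icc21(x, "agreement") == pytest.approx(agr, abs=1e-9)
        assert icc21(x, "consistency") == pytest.approx(cons, abs=1e-9)

    def test_constant_matrix_is_undefined(self):
        assert np.isnan(icc21(np.full((5, 2), 3.0), "agreement"))


class TestNestedBootstrap:
    @staticmethod
    def _pairs(n_subj, n_trials, sd_subj, sd_err, seed, offset=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subj):
            mu = rng.normal(0.0, sd_subj)
            for t in range(n_trials):
                truth = mu + rng.normal(0.0, 0.3)
                rows.append(dict(subject=f"S{s}", trial=t,
                                 value_A=truth + rng.normal(0, sd_err),
                                 value_B=truth + offset + rng.normal(0, sd_err)))
        return pd.DataFrame(rows)

    def test_perfect_agreement_collapses_to_one(self):
        df = self._pairs(10, 3, 2.0, 0.0, seed=7)
        df["value_B"] = df["value_A"]
        out = icc_nested_bootstrap(df, n_boot=500, seed=1)
        assert out["icc_a"] == pytest.approx(1.0, abs=1e-12)
        assert out["icc_a_ci"] == pytest.approx((1.0, 1.0), abs=1e-12)

    def test_single_trial_reduces_to_subject_bootstrap(self):
        df = self._pairs(20, 1, 3.0, 1.0, seed=8)
        out = icc_nested_bootstrap(df, n_boot=10_000, seed=2)
        plug_in = icc21(df[["value_A", "value_B"]].to_numpy(), "agreement")
        assert abs(out["icc_a"] - plug_in) < 0.02

    def test_engineered_variance_ratio_recovers_icc(self):
        # sigma2_subject = 3 * sigma2_error -> consistency ICC = 0.75; a
        # single 50-subject cohort carries ~0.05 SD in the ICC itself, so
        # average over independent cohorts of the same design
        rng = np.random.default_rng(9)
        estimates = []
        for c in range(5):
            rows = []
            for s in range(50):
                mu = rng.normal(0.0, np.sqrt(3.0))
                for t in range(3):
                    rows.append(dict(subject=f"S{s:02d}", trial=t,
                                     value_A=mu + rng.normal(0, 1.0),
                                     value_B=mu + rng.normal(0, 1.0)))
            out = icc_nested_bootstrap(pd.DataFrame(rows), n_boot=1000, seed=c)
            estimates.append(out["icc_c"])
        assert np.mean(estimates) == pytest.approx(0.75, abs=0.05)

    def test_seed_determinism(self):
        df = self._pairs(8, 3, 2.0, 1.0, seed=10)
        a = icc_nested_bootstrap(df, n_boot=200, seed=5)
        b = icc_nested_bootstrap(df, n_boot=200, seed=5)
        assert a == b


class TestRmc:
    def test_single_subject_equals_pearson(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 30)
        b = 0.7 * a + rng.normal(0, 0.5, 30)
        df = pd.DataFrame(dict(subject="S1", trial=0, value_A=a, value_B=b))
        assert rmc(df) == pytest.approx(np.corrcoef(a, b)[0, 1], abs=1e-12)

    def test_within_subject_linearity_gives_one(self):
        rng = np.random.default_rng(12)
        rows = []
        for s, off in enumerate([0.0, 10.0, -4.0]):
            a = rng.normal(0, 1, 20)
            rows.append(pd.DataFrame(dict(subject=f"S{s}", trial=0,
                                          value_A=a, value_B=2.0 * a + off)))
        assert rmc(pd.concat(rows)) == pytest.approx(1.0, abs=1e-12)

    def test_hand_worked_two_subject_value(self):
        # two subjects, three points each; centered series worked by hand:
        # S1: A (1,2,3) -> (-1,0,1), B (2,4,9) -> (-3,-1,4)
        # S2: A (4,6,8) -> (-2,0,2), B (1,2,6) -> (-2,-1,3)
        # r = sum(ab) / sqrt(sum(a^2) sum(b^2)) = 17/sqrt(10*40) = 0.85
        df = pd.DataFrame({
            "subject": ["S1"] * 3 + ["S2"] * 3,
            "trial": 0,
            "value_A": [1.0, 2.0, 3.0, 4.0, 6.0, 8.0],
            "value_B": [2.0, 4.0, 9.0, 1.0, 2.0, 6.0],
        })
        assert rmc(df) == pytest.approx(17.0 / np.sqrt(400.0), abs=1e-12)

    def test_cross_check_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(13)
        rows = []
        for s in range(5):
            a = rng.normal(s, 1, 10)
            rows.append(pd.DataFrame(dict(subject=f"S{s}", trial=np.arange(10),
                                          value_A=a,
                                          value_B=0.6 * a + rng.normal(0, 0.4, 10))))
        df = pd.concat(rows, ignore_index=True)
        expect = pingouin.rm_corr(df, x="value_B", y="value_A", subject="subject")
        assert rmc(df) == pytest.approx(float(expect["r"].iloc[0]), abs=1e-6)

    def test_zero_within_variance_undefined(self):
        df = pd.DataFrame(dict(subject=["S1"] * 3 + ["S2"] * 3, trial=0,
                               value_A=[1.0, 1.0, 1.0, 2.0, 2.0, 2.0],
                               value_B=[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]))
        assert np.isnan(rmc(df))


class TestRmseMixed:
    def test_identity_gives_zero(self):
        rng = np.random.default_rng(14)
        v = rng.normal(0, 5, 40)
        df = pd.DataFrame(dict(subject=np.repeat(np.arange(4), 10), trial=0,
                               value_A=v, value_B=v))
        assert rmse_mixed(df) == pytest.approx(0.0, abs=1e-6)

    def test_known_noise_recovered(self):
        rng = np.random.default_rng(15)
        n = 10_000
        b = rng.normal(50, 10, n)
        df = pd.DataFrame(dict(subject=np.repeat(np.arange(20), n // 20), trial=0,
                               value_A=b + rng.normal(0, 2.0, n), value_B=b))
        assert rmse_mixed(df) == pytest.approx(2.0, rel=0.05)

    def test_subject_offsets_absorbed_by_random_intercept(self):
        rng = np.random.default_rng(16)
        n = 10_000
        subj = np.repeat(np.arange(20), n // 20)
        offsets = rng.normal(0, 5.0, 20)[subj]
        b = rng.normal(50, 10, n)
        df = pd.DataFrame(dict(subject=subj, trial=0,
                               value_A=b + offsets + rng.normal(0, 2.0, n),
                               value_B=b))
        assert rmse_mixed(df) == pytest.approx(2.0, rel=0.05)


class TestLoaThroughRange:
    @staticmethod
    def _frames(diffs_by_trial):
        rows = []
        for (subj, trial), d in diffs_by_trial.items():
            rows.append(pd.DataFrame(dict(subject=subj, trial=trial, diff=d)))
        return pd.concat(rows, ignore_index=True)

    def test_constant_difference_collapses(self):
        frames = self._frames({("S1", 0): np.full(40, 2.0), ("S2", 0): np.full(40, 2.0)})
        assert loa_through_range(frames, n_estimates=10, seed=1) == pytest.approx(
            (2.0, 2.0, 2.0)
        )

    def test_iid_normal_half_width(self):
        rng = np.random.default_rng(17)
        sigma = 3.0
        frames = self._frames({
            (f"S{s}", t): rng.normal(0, sigma, 200)
            for s in range(10) for t in range(3)
        })
        lo, md, hi = loa_through_range(frames, n_estimates=100, k=5, seed=2)
        assert (hi - lo) / 2 == pytest.approx(1.96 * sigma, rel=0.07)

    def test_seed_determinism(self):
        rng = np.random.default_rng(18)
        frames = self._frames({("S1", 0): rng.normal(0, 1, 50),
                               ("S2", 0): rng.normal(0, 1, 50)})
        a = loa_through_range(frames, n_estimates=20, seed=9)
        b = loa_through_range(frames, n_estimates=20, seed=9)
        assert a == b

    def test_short_trial_warns_and_uses_all_frames(self):
        frames = self._frames({("S1", 0): np.array([1.0, 2.0, 3.0]),
                               ("S2", 0): np.arange(10.0)})
        with pytest.warns(UserWarning, match="fewer than"):
            loa_through_range(frames, n_estimates=5, k=5, seed=3)


class TestModelResults:
    @staticmethod
    def _df(seed=19, offset=1.0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(8):
            mu = rng.normal(50, 8)
            for t in range(3):
                truth = mu + rng.normal(0, 2)
                rows.append(dict(subject=f"S{s}", trial=t,
                                 value_A=truth + rng.normal(0, 1.5),
                                 value_B=truth + offset + rng.normal(0, 1.5)))
        return pd.DataFrame(rows)

    def test_fit_populates_peak_point_fields(self):
        res = AgreementModel(self._df()).fit(n_boot=500, seed=4)
        assert res.lloa <= res.md <= res.uloa
        assert res.precision_span >= 0
        assert -1 <= res.icc_a <= 1
        assert res.icc_a_ci[0] <= res.icc_a <= res.icc_a_ci[1] + 1e-9
        assert res.icc_a <= res.icc_c + 0.05  # offset hurts agreement form
        assert res.rmc is None and res.rmse is None
        assert "ICC(2,1) agreement" in res.summary()

    def test_fit_through_range_fields(self):
        rng = np.random.default_rng(20)
        rows = []
        for s in range(5):
            for t in range(2):
                a = rng.normal(40, 10, 60)
                rows.append(pd.DataFrame(dict(subject=f"S{s}", trial=t,
                                              value_A=a,
                                              value_B=a + rng.normal(0, 2, 60))))
        res = AgreementModel(pd.concat(rows), through_range=True).fit(
            n_estimates=30, seed=5
        )
        assert res.icc_a is None
        assert 0.9 < res.rmc <= 1.0
        assert res.rmse == pytest.approx(2.0, rel=0.15)
        assert "repeated-measures corr." in res.summary()

    def test_orientation_flag_flips_md(self):
        df = self._df()
        r1 = AgreementModel(df).fit(n_boot=200, seed=6)
        r2 = AgreementModel(df, orientation="A-B").fit(n_boot=200, seed=6)
        assert r2.md == pytest.approx(-r1.md)
        assert r2.lloa == pytest.approx(-r1.uloa)
        assert r2.icc_a == pytest.approx(r1.icc_a)

    def test_from_dataframe_renames(self):
        df = self._df().rename(columns={"value_A": "reference", "value_B": "markerless",
                                        "subject": "child"})
        m = AgreementModel.from_dataframe(df, value_a="reference", value_b="markerless",
                                          subject="child")
        assert set(AgreementModel.REQUIRED) <= set(m.data.columns)

    def test_rejects_nonfinite(self):
        df = self._df()
        df.loc[0, "value_A"] = np.nan
        with pytest.raises(ValueError, match="finite"):
            AgreementModel(df)
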