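"""Repeated-measures agreement statistics for paired measurement systems.

Implements the method-comparison battery used to judge concurrent validity
of two motion-capture systems measuring the same children simultaneously:

* Bland-Altman limits of agreement (LOA) for repeated measures, with the
  total SD of the differences decomposed into between- and within-subject
  variance components by one-way ANOVA (the "true value varies between
  measurements" variant);
* ICC(2,1) absolute-agreement and consistency forms from two-way ANOVA mean
  squares, with a nested bootstrap (subjects with replacement, then one
  random trial per drawn subject) giving the point estimate as the mean of
  the resamples and percentile confidence intervals;
* the repeated-measures correlation (RMC), the common within-subject
  association after removing subject means;
* a mixed-model RMSE: reference = b0 + b1 * test + u_subject + e, RMSE from
  the conditional residuals;
* a subsampled through-range LOA (k frames per trial, averaged over many
  repetitions) that damps the autocorrelation of per-frame series.

The module follows the statsmodels idiom: build an :class:`AgreementModel`
from a tidy DataFrame of paired values, call :meth:`~AgreementModel.fit`,
and read estimates, intervals, and a ``summary()`` table off the returned
:class:`AgreementResults`.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "AgreementModel",
    "AgreementResults",
    "loa_repeated",
    "icc21",
    "icc_nested_bootstrap",
    "rmc",
    "rmse_mixed",
    "loa_through_range",
]

LOA_MULTIPLIER = 1.96


# ---------------------------------------------------------------------------
# Limits of agreement


def loa_repeated(
    diffs: np.ndarray, subjects: np.ndarray
) -> tuple[float, float, float]:
    """Repeated-measures Bland-Altman limits of agreement.

    Parameters
    ----------
    diffs
        Paired differences (test minus reference by convention).
    subjects
        Subject label per difference; repeated labels mark repeated trials.

    Returns
    -------
    (lloa, md, uloa)
        ``md`` is the grand mean difference; the limits are
        ``md +/- 1.96 * sqrt(sigma2_between + sigma2_within)`` with the
        variance components from one-way ANOVA of the differences on
        subject.  With one difference per subject this reduces exactly to
        the classic Bland-Altman mean +/- 1.96 SD.
    """
    d = np.asarray(diffs, dtype=float)
    subjects = np.asarray(subjects)
    if d.shape[0] != subjects.shape[0]:
        raise ValueError("diffs and subjects must have equal length")
    if d.shape[0] < 2:
        raise ValueError("need at least two paired differences")
    md = float(np.mean(d))
    labels, inverse, counts = np.unique(subjects, return_inverse=True, return_counts=True)
    m = labels.shape[0]
    big_n = d.shape[0]
    if m == 1:
        warnings.warn("single subject: falling back to classic Bland-Altman SD")
        sd = float(np.std(d, ddof=1))
    elif big_n == m:
        # one pair per subject: no within-subject stratum
        sd = float(np.std(d, ddof=1))
    else:
        group_means = np.bincount(inverse, weights=d) / counts
        ss_within = float(np.sum((d - group_means[inverse]) ** 2))
        ss_between = float(np.sum(counts * (group_means - md) ** 2))
        df_within = big_n - m
        df_between = m - 1
        msw = ss_within / df_within if df_within > 0 else 0.0
        msb = ss_between / df_between
        # unbalanced one-way ANOVA: expected MSB = sigma2_w + n0 * sigma2_b
        n0 = (big_n - float(np.sum(counts**2)) / big_n) / df_between
        sigma2_b = max(0.0, (msb - msw) / n0)
        sd = float(np.sqrt(sigma2_b + msw))
    half = LOA_MULTIPLIER * sd
    return md - half, md, md + half


def loa_through_range(
    frames: pd.DataFrame,
    n_estimates: int = 100,
    k: int = 5,
    seed: int | None = None,
    diff_col: str = "diff",
) -> tuple[float, float, float]:
    """Through-range LOA by repeated per-trial frame subsampling.

    ``frames`` holds per-frame paired differences with ``subject`` and
    ``trial`` columns.  Each of ``n_estimates`` repetitions samples ``k``
    frames uniformly without replacement from every trial (a short trial
    contributes all its frames, with a warning), runs :func:`loa_repeated`
    on the reduced set, and the three limits are averaged over repetitions.
    Subsampling breaks the frame-to-frame autocorrelation that would
    otherwise understate the within-subject degrees of freedom.
    """
    rng = np.random.default_rng(seed)
    groups = [
        (str(subj), np.asarray(g[diff_col], dtype=float))
        for (subj, _), g in frames.groupby(["subject", "trial"], sort=True)
    ]
    if any(v.shape[0] < k for _, v in groups):
        warnings.warn(f"some trials have fewer than k={k} frames; using all their frames")
    acc = np.zeros(3)
    for _ in range(n_estimates):
        ds, ss = [], []
        for subj, vals in groups:
            take = min(k, vals.shape[0])
            idx = rng.choice(vals.shape[0], size=take, replace=False)
            ds.append(vals[idx])
            ss.extend([subj] * take)
        lo, md, hi = loa_repeated(np.concatenate(ds), np.array(ss))
        acc += (lo, md, hi)
    lo, md, hi = acc / n_estimates
    return float(lo), float(md), float(hi)


# ---------------------------------------------------------------------------
# Intraclass correlation


def _icc21_stack(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(agreement, consistency) ICC(2,1) for stacked (..., n, k) matrices."""
    n, k = x.shape[-2], x.shape[-1]
    grand = x.mean(axis=(-1, -2), keepdims=True)
    rows = x.mean(axis=-1, keepdims=True)
    cols = x.mean(axis=-2, keepdims=True)
    ssr = k * ((rows - grand) ** 2).sum(axis=(-1, -2))
    ssc = n * ((cols - grand) ** 2).sum(axis=(-1, -2))
    sst = ((x - grand) ** 2).sum(axis=(-1, -2))
    sse = np.maximum(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    # a (near-)constant matrix has no variance to partition: undefined, not
    # a ratio of roundoff residue
    scale = np.abs(x).max(axis=(-1, -2))
    degenerate = sst <= (n * k) * (1e-12 * (1.0 + scale)) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        denom_c = msr + (k - 1) * mse
        cons = np.where(~degenerate & (denom_c > 0), (msr - mse) / denom_c, np.nan)
        denom_a = denom_c + (k / n) * (msc - mse)
        agr = np.where(~degenerate & (denom_a != 0), (msr - mse) / denom_a, np.nan)
    return agr, cons


def icc21(matrix: np.ndarray, form: str = "agreement") -> float:
    """Single-measure two-way random-effects ICC(2,1) from ANOVA mean squares.

    ``matrix`` is subjects x raters with no missing cells.  The consistency
    form is ``(MSR - MSE) / (MSR + (k-1) MSE)``; the absolute-agreement form
    adds ``(k/n)(MSC - MSE)`` to the denominator, penalising systematic
    rater offsets.  A constant matrix is undefined and returns NaN.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("matrix must be (n >= 2 subjects) x (k >= 2 raters)")
    if not np.all(np.isfinite(x)):
        raise ValueError("matrix must have no missing cells")
    agr, cons = _icc21_stack(x)
    if form == "agreement":
        return float(agr)
    if form == "consistency":
        return float(cons)
    raise ValueError(f"form must be 'agreement' or 'consistency', got {form!r}")


def icc_nested_bootstrap(
    pairs: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int | None = None,
    skip_warn_frac: float = 0.10,
) -> dict:
    """Nested-bootstrap ICC(2,1) for subjects measured in repeated trials.

    Each resample draws subjects with replacement and represents every drawn
    subject by one randomly selected trial, yielding an n x 2 matrix on
    which both ICC forms are computed.  The reported point estimates are the
    means over the resamples; intervals are the 2.5 and 97.5 percentiles.
    Resamples with an undefined ICC are skipped and counted.

    ``pairs`` needs columns ``subject``, ``trial``, ``value_A``, ``value_B``.
    """
    rng = np.random.default_rng(seed)
    per_subject = [
        g[["value_A", "value_B"]].to_numpy(dtype=float)
        for _, g in pairs.groupby("subject", sort=True)
    ]
    n = len(per_subject)
    if n < 2:
        raise ValueError("need >= 2 subjects")
    max_t = max(a.shape[0] for a in per_subject)
    padded = np.zeros((n, max_t, 2))
    counts = np.zeros(n, dtype=int)
    for i, a in enumerate(per_subject):
        padded[i, : a.shape[0]] = a
        counts[i] = a.shape[0]

    subj_idx = rng.integers(0, n, size=(n_boot, n))
    trial_idx = (rng.random(size=(n_boot, n)) * counts[subj_idx]).astype(int)
    samples = padded[subj_idx, trial_idx]  # (n_boot, n, 2)
    agr, cons = _icc21_stack(samples)

    out: dict = {"n_boot": n_boot}
    for name, vals in (("icc_a", agr), ("icc_c", cons)):
        ok = vals[np.isfinite(vals)]
        skipped = n_boot - ok.shape[0]
        if skipped > skip_warn_frac * n_boot:
            warnings.warn(f"{name}: {skipped}/{n_boot} resamples had undefined ICC")
        out[name] = float(np.mean(ok)) if ok.size else float("nan")
        out[f"{name}_ci"] = (
            (float(np.percentile(ok, 2.5)), float(np.percentile(ok, 97.5)))
            if ok.size
            else (float("nan"), float("nan"))
        )
        out[f"{name}_skipped"] = int(skipped)
    return out


# ---------------------------------------------------------------------------
# Repeated-measures correlation and mixed-model RMSE


def rmc(pairs: pd.DataFrame) -> float:
    """Repeated-measures correlation: common within-subject association.

    Centers each subject's A and B values on its own means and returns the
    Pearson correlation of the pooled centered values (the ANCOVA partial
    correlation with subject as factor).  Zero within-subject variance in
    either series is undefined and returns NaN.
    """
    g = pairs.groupby("subject")
    a = pairs["value_A"].to_numpy(float) - g["value_A"].transform("mean").to_numpy(float)
    b = pairs["value_B"].to_numpy(float) - g["value_B"].transform("mean").to_numpy(float)
    if np.allclose(a, 0) or np.allclose(b, 0):
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def rmse_mixed(pairs: pd.DataFrame) -> float:
    """RMSE of a random-intercept mixed model reference ~ test.

    Fits ``value_A = b0 + b1 * value_B + u_subject + e`` (REML) and returns
    the root mean square of the conditional residuals, so that constant
    per-subject offsets are absorbed by the random intercept rather than
    inflating the error.  Falls back to ordinary least squares with a
    warning if the mixed model does not converge.
    """
    df = pairs[["subject", "value_A", "value_B"]].copy()
    if df["subject"].nunique() < 2:
        raise ValueError("need >= 2 subjects for the mixed model")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.mixedlm("value_A ~ value_B", df, groups=df["subject"]).fit(reml=True)
        if not res.converged:
            raise RuntimeError("mixed model did not converge")
        resid = np.asarray(res.resid)  # conditional residuals (incl. random effects)
    except (np.linalg.LinAlgError, RuntimeError, ValueError):
        warnings.warn("mixed model failed; falling back to fixed-intercept OLS")
        x = sm.add_constant(df["value_B"].to_numpy(float))
        resid = sm.OLS(df["value_A"].to_numpy(float), x).fit().resid
    return float(np.sqrt(np.mean(resid**2)))


# ---------------------------------------------------------------------------
# Model / Results


class AgreementModel:
    """Agreement analysis between two systems measuring the same trials.

    Parameters
    ----------
    data
        Tidy DataFrame with columns ``subject``, ``trial``, ``value_A``
        (reference system), ``value_B`` (test system).  For through-range
        analyses there is one row per frame per trial.
    through_range
        When True, :meth:`fit` uses the frame-subsampled LOA and adds RMC
        and the mixed-model RMSE; when False (peak/point values) it uses
        the repeated-measures LOA and the nested-bootstrap ICCs.
    orientation
        ``"B-A"`` (default, test minus reference) or ``"A-B"``.
    """

    REQUIRED = ("subject", "trial", "value_A", "value_B")

    def __init__(
        self,
        data: pd.DataFrame,
        through_range: bool = False,
        orientation: str = "B-A",
    ) -> None:
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"data lacks required columns: {missing}")
        if orientation not in ("B-A", "A-B"):
            raise ValueError("orientation must be 'B-A' or 'A-B'")
        data = data.copy()
        if not np.all(np.isfinite(data[["value_A", "value_B"]].to_numpy(float))):
            raise ValueError("paired values must be finite")
        self.data = data
        self.through_range = through_range
        self.orientation = orientation

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        value_a: str = "value_A",
        value_b: str = "value_B",
        subject: str = "subject",
        trial: str = "trial",
        **kwargs,
    ) -> "AgreementModel":
        """Build from a DataFrame with custom column names."""
        renamed = df.rename(
            columns={value_a: "value_A", value_b: "value_B", subject: "subject", trial: "trial"}
        )
        return cls(renamed, **kwargs)

    @property
    def diffs(self) -> np.ndarray:
        d = self.data["value_B"].to_numpy(float) - self.data["value_A"].to_numpy(float)
        return d if self.orientation == "B-A" else -d

    def fit(
        self,
        n_boot: int = 10_000,
        n_estimates: int = 100,
        k_frames: int = 5,
        seed: int | None = None,
    ) -> "AgreementResults":
        """Run the battery and return an :class:`AgreementResults`."""
        data = self.data
        subjects = data["subject"].to_numpy()
        d = self.diffs
        n_subjects = int(data["subject"].nunique())
        if self.through_range:
            frames = data.assign(diff=d)
            lloa, md, uloa = loa_through_range(
                frames, n_estimates=n_estimates, k=k_frames, seed=seed
            )
            rmc_val = rmc(data)
            rmse_val = rmse_mixed(data)
            boot = None
        else:
            lloa, md, uloa = loa_repeated(d, subjects)
            boot = icc_nested_bootstrap(data, n_boot=n_boot, seed=seed)
            rmc_val = rmse_val = None
        return AgreementResults(
            model=self,
            md=md,
            lloa=lloa,
            uloa=uloa,
            icc_a=None if boot is None else boot["icc_a"],
            icc_a_ci=None if boot is None else boot["icc_a_ci"],
            icc_c=None if boot is None else boot["icc_c"],
            icc_c_ci=None if boot is None else boot["icc_c_ci"],
            rmc=rmc_val,
            rmse=rmse_val,
            n_subjects=n_subjects,
            n_pairs=int(data.shape[0]),
        )


@dataclasses.dataclass
class AgreementResults:
    """Fitted agreement estimates for one variable/measurement-type cell."""

    model: AgreementModel
    md: float
    lloa: float
    uloa: float
    icc_a: float | None
    icc_a_ci: tuple[float, float] | None
    icc_c: float | None
    icc_c_ci: tuple[float, float] | None
    rmc: float | None
    rmse: float | None
    n_subjects: int
    n_pairs: int

    @property
    def precision_span(self) -> float:
        """Half-width of the LOA interval, (ULoA - LLoA) / 2."""
        return (self.uloa - self.lloa) / 2.0

    def to_dict(self) -> dict:
        out = {
            "lloa": self.lloa, "md": self.md, "uloa": self.uloa,
            "precision_span": self.precision_span,
            "n_subjects": self.n_subjects, "n_pairs": self.n_pairs,
        }
        if self.icc_a is not None:
            out.update(
                icc_a=self.icc_a, icc_a_ci_lo=self.icc_a_ci[0], icc_a_ci_hi=self.icc_a_ci[1],
                icc_c=self.icc_c, icc_c_ci_lo=self.icc_c_ci[0], icc_c_ci_hi=self.icc_c_ci[1],
            )
        if self.rmc is not None:
            out.update(rmc=self.rmc, rmse=self.rmse)
        return out

    def summary(self) -> str:
        """Human-readable summary table."""
        lines = [
            "Agreement analysis (B - A difference orientation: "
            f"{self.model.orientation})",
            "=" * 58,
            f"{'n subjects':<28}{self.n_subjects:>12}",
            f"{'n pairs':<28}{self.n_pairs:>12}",
            f"{'mean difference (MD)':<28}{self.md:>12.3f}",
            f"{'lower LOA':<28}{self.lloa:>12.3f}",
            f"{'upper LOA':<28}{self.uloa:>12.3f}",
            f"{'precision span (half-width)':<28}{self.precision_span:>12.3f}",
        ]
        if self.icc_a is not None:
            lines += [
                f"{'ICC(2,1) agreement':<28}{self.icc_a:>12.3f}"
                f"   [{self.icc_a_ci[0]:.3f}; {self.icc_a_ci[1]:.3f}]",
                f"{'ICC(2,1) consistency':<28}{self.icc_c:>12.3f}"
                f"   [{self.icc_c_ci[0]:.3f}; {self.icc_c_ci[1]:.3f}]",
            ]
        if self.rmc is not None:
            lines += [
                f"{'repeated-measures corr.':<28}{self.rmc:>12.3f}",
                f"{'mixed-model RMSE':<28}{self.rmse:>12.3f}",
            ]
        lines.append("=" * 58)
        return "\n".join(lines)
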