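"""Cohort statistics: reproducibility, distribution tests, screened regression.

Implements the analysis workflow around the CSDIs:

* inter-observer reproducibility of subfield mean thickness — single-measure
  intraclass correlation from a two-way random-effects model under absolute
  agreement (ICC(A,1), a.k.a. ICC2) with its F-based confidence interval,
  Bland–Altman 95% limits of agreement, and the coefficient of
  reproducibility CR = 1.96·SD(paired differences);
* distribution checks for the CSDIs — one-sample t against 0, Shapiro–Wilk,
  and a Kolmogorov–Smirnov test with estimated mean/SD whose p-value is
  Lilliefors-corrected via a seeded Monte-Carlo null (a plain KS p against
  the fitted normal is available behind a flag);
* the covariate screen — univariate OLS per covariate, carrying those with
  P < 0.10 into a single multivariable OLS, reporting standardized betas
  (outcome-SD units per covariate-SD) at both stages.  Binary covariates
  are coded 0/1 and standardized like continuous ones.  No multiple-testing
  correction is applied, matching common practice for this screen; the
  final p-values therefore inherit the selection step's optimism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # pingouin's import-time deprecation chatter
    import pingouin

import statsmodels.api as sm


# ---------------------------------------------------------------------------
# reproducibility


@dataclass(frozen=True)
class ICCResult:
    """Single-measure two-way random absolute-agreement ICC with 95% CI."""

    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_raters: int


@dataclass(frozen=True)
class BlandAltmanResult:
    """Paired-difference agreement summary (units of the ratings)."""

    mean_diff: float
    loa_low: float
    loa_high: float
    cr: float
    n: int


def _as_ratings(ratings) -> np.ndarray:
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[1] != 2:
        raise ValueError(f"ratings must be an (n, 2) array, got shape {r.shape}")
    if not np.isfinite(r).all():
        raise ValueError("ratings contain missing or non-finite cells")
    return r


def icc_absolute_agreement(ratings) -> ICCResult:
    """ICC(A,1): two-way random effects, absolute agreement, single measure.

    From the two-way ANOVA mean squares with k raters,
    ICC = (MS_rows − MS_err) / (MS_rows + (k−1)·MS_err + (k/n)(MS_cols − MS_err)),
    with the standard F-based 95% confidence interval.

    Parameters
    ----------
    ratings : array-like, shape (n_subjects, 2)
        One column per observer.

    Raises
    ------
    ValueError
        For fewer than 3 subjects, missing cells, or zero total variance
        (the ICC is undefined).
    """
    r = _as_ratings(ratings)
    n = r.shape[0]
    if n < 3:
        raise ValueError(f"ICC needs at least 3 subjects, got {n}")
    if np.var(r) == 0:
        raise ValueError("ICC undefined: ratings have zero total variance")
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), 2),
            "rater": np.tile(["A", "B"], n),
            "score": r.reshape(-1),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance warnings on degenerate CIs
        table = pingouin.intraclass_corr(
            data=long, targets="subject", raters="rater", ratings="score"
        )
    icc = float(table.set_index("Type").loc["ICC(A,1)", "ICC"])
    ci_low, ci_high = _icc_a1_ci(r, icc)
    return ICCResult(
        icc=icc,
        ci_low=ci_low,
        ci_high=ci_high,
        n_subjects=n,
        n_raters=2,
    )


def _icc_a1_ci(r: np.ndarray, icc: float, alpha: float = 0.05) -> tuple[float, float]:
    """F-based CI for single-measure absolute-agreement ICC (McGraw & Wong).

    Computed at full precision from the two-way ANOVA mean squares with a
    Satterthwaite-approximated denominator df.
    """
    n, k = r.shape
    grand = r.mean()
    ss_rows = k * ((r.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((r.mean(axis=0) - grand) ** 2).sum()
    ss_err = ((r - grand) ** 2).sum() - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    if mse == 0 and msc == 0:
        return (icc, icc)  # perfect agreement: degenerate interval
    denom = n * (1.0 - icc)
    if denom <= 0:
        return (icc, icc)
    a = k * icc / denom
    b = 1.0 + k * icc * (n - 1) / denom
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f1 = scipy.stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = scipy.stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f1 * mse) / (
        f1 * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f2 * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2 * msr
    )
    return (float(lower), float(upper))


def bland_altman(ratings) -> BlandAltmanResult:
    """Bland–Altman agreement of two observers.

    d = A − B per subject; limits of agreement are mean(d) ± 1.96·SD(d) and
    the coefficient of reproducibility is CR = 1.96·SD(d) (sample SD,
    ddof = 1).
    """
    r = _as_ratings(ratings)
    if r.shape[0] < 2:
        raise ValueError("Bland–Altman needs at least 2 paired values")
    d = r[:, 0] - r[:, 1]
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    cr = 1.96 * sd
    return BlandAltmanResult(
        mean_diff=mean_diff,
        loa_low=mean_diff - cr,
        loa_high=mean_diff + cr,
        cr=cr,
        n=r.shape[0],
    )


def reproducibility_report(paired: pd.DataFrame, value: str = "mean_thickness_um") -> pd.DataFrame:
    """Per-subfield ICC + Bland–Altman from a tidy paired table.

    ``paired`` needs columns subject, observer (exactly two levels),
    subfield, and the value column.  Returns one row per subfield.
    """
    observers = sorted(paired["observer"].unique())
    if len(observers) != 2:
        raise ValueError(f"expected exactly 2 observers, found {observers}")
    rows = []
    for subfield, g in paired.groupby("subfield", sort=False):
        wide = g.pivot(index="subject", columns="observer", values=value)
        if wide.isna().any().any():
            raise ValueError(f"subfield {subfield}: missing observer cells")
        arr = wide[observers].to_numpy()
        icc = icc_absolute_agreement(arr)
        ba = bland_altman(arr)
        rows.append(
            {
                "subfield": subfield,
                "n": icc.n_subjects,
                "icc": icc.icc,
                "icc_ci_low": icc.ci_low,
                "icc_ci_high": icc.ci_high,
                "mean_diff_um": ba.mean_diff,
                "loa_low_um": ba.loa_low,
                "loa_high_um": ba.loa_high,
                "cr_um": ba.cr,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# distribution tests


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    n: int
    mean: float
    sd: float


def one_sample_t(values, test_value: float = 0.0) -> TTestResult:
    """Two-sided one-sample t-test of mean(values) against ``test_value``."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("one_sample_t needs a 1-D sample with n >= 2")
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("one_sample_t undefined for a zero-variance sample")
    res = scipy.stats.ttest_1samp(x, popmean=test_value)
    return TTestResult(
        t=float(res.statistic), p=float(res.pvalue), n=x.size,
        mean=float(x.mean()), sd=sd,
    )


def _ks_statistic_normal(sorted_z: np.ndarray) -> np.ndarray:
    """Row-wise KS distance of standardized, sorted samples to Φ."""
    n = sorted_z.shape[-1]
    cdf = scipy.stats.norm.cdf(sorted_z)
    grid_hi = np.arange(1, n + 1) / n
    grid_lo = np.arange(0, n) / n
    d_plus = (grid_hi - cdf).max(axis=-1)
    d_minus = (cdf - grid_lo).max(axis=-1)
    return np.maximum(d_plus, d_minus)


@dataclass(frozen=True)
class NormalityResult:
    ks_stat: float
    ks_p: float
    shapiro_stat: float
    shapiro_p: float
    n: int
    lilliefors: bool


def normality_tests(
    values,
    seed: int = 0,
    n_mc: int = 10_000,
    lilliefors: bool = True,
) -> NormalityResult:
    """Kolmogorov–Smirnov and Shapiro–Wilk normality tests.

    The KS statistic is computed against a normal with the sample's
    estimated mean and SD.  Because the parameters are estimated, the
    classical KS null is wrong (anti-conservative p); by default the
    p-value is therefore Lilliefors-corrected with a seeded Monte-Carlo
    null of ``n_mc`` standard-normal samples of the same size.  Set
    ``lilliefors=False`` for the naive KS p against the fitted normal.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("normality_tests needs a 1-D sample with n >= 4")
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("normality tests undefined for a constant sample")
    n = x.size
    z = np.sort((x - x.mean()) / sd)
    ks_stat = float(_ks_statistic_normal(z))
    if lilliefors:
        rng = np.random.default_rng(seed)
        null = rng.normal(size=(n_mc, n))
        null = (null - null.mean(axis=1, keepdims=True)) / null.std(
            axis=1, ddof=1, keepdims=True
        )
        null_stats = _ks_statistic_normal(np.sort(null, axis=1))
        ks_p = float((1 + (null_stats >= ks_stat).sum()) / (n_mc + 1))
    else:
        ks_p = float(scipy.stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue)
    sw = scipy.stats.shapiro(x)
    return NormalityResult(
        ks_stat=ks_stat,
        ks_p=ks_p,
        shapiro_stat=float(sw.statistic),
        shapiro_p=float(sw.pvalue),
        n=n,
        lilliefors=lilliefors,
    )


# ---------------------------------------------------------------------------
# screened regression


@dataclass
class RegressionReport:
    """Two-stage association analysis for one outcome.

    ``table`` has one row per candidate covariate: univariate standardized
    beta and p, the screen flag (univariate p < screen_alpha), and — for
    screened covariates — the multivariable standardized beta and p.
    """

    outcome: str
    n: int
    screen_alpha: float
    table: pd.DataFrame

    @property
    def screened(self) -> list[str]:
        return list(self.table.loc[self.table["screened"], "covariate"])

    def reported_beta(self, covariate: str) -> float:
        """The pipeline's reported association: multivariable when screened
        in, univariate otherwise."""
        row = self.table.set_index("covariate").loc[covariate]
        if bool(row["screened"]):
            return float(row["multi_beta"])
        return float(row["uni_beta"])


def _zscore(a: np.ndarray) -> np.ndarray:
    return (a - a.mean()) / a.std(ddof=1)


def screened_regression(
    cohort: pd.DataFrame,
    outcome: str,
    covariates: list[str] | None = None,
    screen_alpha: float = 0.10,
    cond_threshold: float = 1e8,
) -> RegressionReport:
    """Univariate screen at P < ``screen_alpha`` feeding a multivariable OLS.

    All variables are z-scored on the sample (ddof = 1) before fitting, so
    the OLS coefficients are standardized betas; p-values are identical to
    the unstandardized fits.  Complete cases only.

    Raises
    ------
    ValueError
        If the screened design is ill-conditioned (condition number above
        ``cond_threshold``), naming the screened covariates.
    """
    if covariates is None:
        covariates = [
            c
            for c in cohort.columns
            if c not in ("subject", outcome) and pd.api.types.is_numeric_dtype(cohort[c])
        ]
    missing = [c for c in [outcome, *covariates] if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns: {', '.join(missing)}")
    data = cohort[[outcome, *covariates]].dropna()
    n = len(data)
    if n < 10 * max(1, len(covariates)):
        warnings.warn(
            f"only {n} complete cases for {len(covariates)} candidate "
            "covariates (< 10 per covariate)",
            RuntimeWarning,
            stacklevel=2,
        )
    y = _zscore(data[outcome].to_numpy(dtype=float))

    rows = []
    z_cols: dict[str, np.ndarray] = {}
    for c in covariates:
        xc = data[c].to_numpy(dtype=float)
        if xc.std(ddof=1) == 0:
            raise ValueError(f"covariate {c} is constant in the complete cases")
        z = _zscore(xc)
        z_cols[c] = z
        fit = sm.OLS(y, sm.add_constant(z)).fit()
        p = float(fit.pvalues[1])
        rows.append(
            {
                "covariate": c,
                "uni_beta": float(fit.params[1]),
                "uni_p": p,
                "screened": p < screen_alpha,
                "multi_beta": np.nan,
                "multi_p": np.nan,
            }
        )
    table = pd.DataFrame(rows)

    screened = list(table.loc[table["screened"], "covariate"])
    if screened:
        X = np.column_stack([z_cols[c] for c in screened])
        cond = float(np.linalg.cond(X))
        if cond > cond_threshold:
            raise ValueError(
                f"screened covariates are collinear (condition number "
                f"{cond:.3g}): {', '.join(screened)}"
            )
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        for j, c in enumerate(screened, start=1):
            table.loc[table["covariate"] == c, "multi_beta"] = float(fit.params[j])
            table.loc[table["covariate"] == c, "multi_p"] = float(fit.pvalues[j])

    return RegressionReport(outcome=outcome, n=n, screen_alpha=screen_alpha, table=table)
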