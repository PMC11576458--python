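"""Method-agreement statistics comparing the two EEG systems.

Bland-Altman analysis treats the wet (gel) system as the gold standard:
for each measure the per-subject difference wet - dry is summarized by
its mean (bias), 95 % confidence interval of the bias (t quantile by
default), and 95 % limits of agreement bias +- 1.96 * SD with their own
confidence intervals.  A bias CI excluding zero flags a systematic
difference between systems.  The comparison layer also provides the
2 x 2 fully-within-subject ANOVA (system x tone), paired t-tests (one- or
two-sided, Bonferroni-corrected), the Wilcoxon signed-rank alternative,
and effect sizes (paired Cohen's d, partial eta squared).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PairedMeasures:
    """Per-subject paired scalars for one measure; incomplete pairs are
    dropped (and counted) on construction."""

    subject_id: List
    value_wet: np.ndarray
    value_dry: np.ndarray
    measure_name: str = ""
    units: str = ""
    n_dropped: int = 0

    def __post_init__(self):
        w = np.asarray(self.value_wet, float)
        d = np.asarray(self.value_dry, float)
        if len(self.subject_id) != w.size or w.size != d.size:
            raise ValueError("subject_id, value_wet, value_dry must align")
        ok = np.isfinite(w) & np.isfinite(d)
        self.n_dropped = int((~ok).sum())
        self.subject_id = [s for s, k in zip(self.subject_id, ok) if k]
        self.value_wet = w[ok]
        self.value_dry = d[ok]

    @property
    def n(self) -> int:
        return self.value_wet.size

    def diffs(self, reference_first: bool = True) -> np.ndarray:
        """wet - dry by default (negative bias: dry overestimates)."""
        d = self.value_wet - self.value_dry
        return d if reference_first else -d


@dataclass
class AgreementResult:
    bias: float
    bias_ci: Tuple[float, float]
    loa_low: float
    loa_high: float
    loa_low_ci: Tuple[float, float]
    loa_high_ci: Tuple[float, float]
    n: int
    sd_diff: float
    measure_name: str = ""
    sign_convention: str = "wet - dry"

    @property
    def bias_significant(self) -> bool:
        lo, hi = self.bias_ci
        return not (lo <= 0.0 <= hi)


@dataclass
class TestResult:
    name: str
    statistic: float
    df: float
    p: float
    effect_size: Tuple[str, float]
    sided: str = "two"
    correction: str = "none"
    effect_label: Optional[str] = None


def effect_size_label(d: float) -> str:
    """Cohen's convention with 'negligible' below the small threshold."""
    a = abs(d)
    if a < 0.2:
        return "negligible"
    if a < 0.5:
        return "small"
    if a < 0.8:
        return "moderate"
    return "large"


def cohens_d_paired(diffs: np.ndarray) -> float:
    """Paired Cohen's d: mean difference over its SD (n-1 denominator)."""
    diffs = np.asarray(diffs, float)
    sd = diffs.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("zero variance of differences")
    return float(diffs.mean() / sd)


def partial_eta_sq(ss_effect: float, ss_error: float) -> float:
    return float(ss_effect / (ss_effect + ss_error))


def bland_altman(pm: PairedMeasures, reference_first: bool = True,
                 loa_multiplier: float = 1.96,
                 ci_quantile: str = "t") -> AgreementResult:
    """Bland-Altman bias, bias CI and 95 % limits of agreement.

    bias = mean(diff); sd = sample SD (n-1); LoA = bias +- 1.96 sd;
    bias CI = bias +- q * sd / sqrt(n); LoA CI = LoA +- q * sd * sqrt(3/n)
    with q the 97.5 % t (default) or normal quantile.
    """
    if pm.n < 3:
        raise ValueError("Bland-Altman needs at least 3 complete pairs")
    diffs = pm.diffs(reference_first)
    n = pm.n
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    q = stats.t.ppf(0.975, n - 1) if ci_quantile == "t" else stats.norm.ppf(0.975)
    half = q * sd / np.sqrt(n)
    loa_half = q * sd * np.sqrt(3.0 / n)
    lo = bias - loa_multiplier * sd
    hi = bias + loa_multiplier * sd
    return AgreementResult(
        bias=bias, bias_ci=(bias - half, bias + half),
        loa_low=lo, loa_high=hi,
        loa_low_ci=(lo - loa_half, lo + loa_half),
        loa_high_ci=(hi - loa_half, hi + loa_half),
        n=n, sd_diff=sd, measure_name=pm.measure_name,
        sign_convention="wet - dry" if reference_first else "dry - wet",
    )


def rm_anova_2x2(values: np.ndarray,
                 factor_names: Tuple[str, str] = ("system", "tone"),
                 ) -> List[TestResult]:
    """Fully within-subject 2 x 2 repeated-measures ANOVA.

    ``values`` has shape (n_subjects, 2, 2) indexed (subject, A, B).
    Each effect (A, B, A x B) is tested against its own subject-by-effect
    error term with df = (1, n - 1); effect size is partial eta squared.
    """
    y = np.asarray(values, float)
    if y.ndim != 3 or y.shape[1:] != (2, 2):
        raise ValueError("values must have shape (n_subjects, 2, 2)")
    if not np.all(np.isfinite(y)):
        raise ValueError("incomplete cells")
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")

    grand = y.mean()
    subj = y.mean(axis=(1, 2))            # per-subject means
    a_m = y.mean(axis=(0, 2))             # factor A level means
    b_m = y.mean(axis=(0, 1))
    ab_m = y.mean(axis=0)                 # cell means
    ia_m = y.mean(axis=2)                 # subject x A
    ib_m = y.mean(axis=1)                 # subject x B

    ss_a = 2 * n * np.sum((a_m - grand) ** 2)
    ss_b = 2 * n * np.sum((b_m - grand) ** 2)
    ss_ab = n * np.sum((ab_m - a_m[:, None] - b_m[None, :] + grand) ** 2)
    ss_as = 2 * np.sum((ia_m - subj[:, None] - a_m[None, :] + grand) ** 2)
    ss_bs = 2 * np.sum((ib_m - subj[:, None] - b_m[None, :] + grand) ** 2)
    resid = (y - ia_m[:, :, None] - ib_m[:, None, :] - ab_m[None, :, :]
             + subj[:, None, None] + a_m[None, :, None] + b_m[None, None, :]
             - grand)
    ss_abs = np.sum(resid**2)

    # guard against pure floating-point residue in degenerate (constant)
    # tables: sums of squares below this are treated as exactly zero
    tiny = 1e-15 * max(float(np.sum(y * y)), np.finfo(float).tiny)

    out = []
    for name, ss_eff, ss_err in [
        (factor_names[0], ss_a, ss_as),
        (factor_names[1], ss_b, ss_bs),
        (f"{factor_names[0]} x {factor_names[1]}", ss_ab, ss_abs),
    ]:
        ss_eff = 0.0 if ss_eff < tiny else ss_eff
        ss_err = 0.0 if ss_err < tiny else ss_err
        df_err = n - 1
        ms_eff = ss_eff / 1.0
        ms_err = ss_err / df_err
        f = ms_eff / ms_err if ms_err > 0 else 0.0
        p = float(stats.f.sf(f, 1, df_err)) if ms_err > 0 else 1.0
        eta = partial_eta_sq(ss_eff, ss_err) if (ss_eff + ss_err) > 0 else 0.0
        out.append(TestResult(name=name, statistic=float(f), df=df_err, p=p,
                              effect_size=("partial_eta_sq", float(eta))))
    return out


def anova_sums_of_squares(values: np.ndarray) -> dict:
    """All sums of squares of the 2 x 2 within decomposition, for
    checking that they add up to the total."""
    y = np.asarray(values, float)
    n = y.shape[0]
    grand = y.mean()
    subj = y.mean(axis=(1, 2))
    a_m = y.mean(axis=(0, 2))
    b_m = y.mean(axis=(0, 1))
    ab_m = y.mean(axis=0)
    ia_m = y.mean(axis=2)
    ib_m = y.mean(axis=1)
    resid = (y - ia_m[:, :, None] - ib_m[:, None, :] - ab_m[None, :, :]
             + subj[:, None, None] + a_m[None, :, None] + b_m[None, None, :]
             - grand)
    return dict(
        total=np.sum((y - grand) ** 2),
        subjects=4 * np.sum((subj - grand) ** 2),
        a=2 * n * np.sum((a_m - grand) ** 2),
        b=2 * n * np.sum((b_m - grand) ** 2),
        ab=n * np.sum((ab_m - a_m[:, None] - b_m[None, :] + grand) ** 2),
        a_err=2 * np.sum((ia_m - subj[:, None] - a_m[None, :] + grand) ** 2),
        b_err=2 * np.sum((ib_m - subj[:, None] - b_m[None, :] + grand) ** 2),
        ab_err=np.sum(resid**2),
    )


def paired_tests(pm: PairedMeasures, sided: str = "two",
                 direction: str = "less", bonferroni_m: int = 1) -> TestResult:
    """Paired t-test on wet - dry differences.

    ``direction`` applies to one-sided tests and states the alternative
    for the mean difference ('less': wet < dry).  Bonferroni correction
    multiplies p by ``bonferroni_m`` (capped at 1).
    """
    diffs = pm.diffs()
    n = diffs.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    sd = diffs.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("zero variance of differences")
    t = diffs.mean() / (sd / np.sqrt(n))
    df = n - 1
    if sided == "two":
        p = 2 * stats.t.sf(abs(t), df)
    elif direction == "less":
        p = stats.t.cdf(t, df)
    else:
        p = stats.t.sf(t, df)
    p = float(min(1.0, bonferroni_m * p))
    d = cohens_d_paired(diffs)
    return TestResult(
        name=f"paired t ({pm.measure_name})", statistic=float(t), df=df, p=p,
        effect_size=("cohen_d", d), sided=sided,
        correction="bonferroni" if bonferroni_m > 1 else "none",
        effect_label=effect_size_label(d),
    )


def wilcoxon_signed_rank(pm: PairedMeasures, sided: str = "two",
                         direction: str = "less") -> TestResult:
    """Wilcoxon signed-rank test on wet - dry differences.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 and a continuity-corrected normal approximation above.
    """
    diffs = pm.diffs()
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        raise ValueError("all differences are zero")
    alternative = "two-sided" if sided == "two" else direction
    method = "exact" if n <= 25 else "approx"
    res = stats.wilcoxon(diffs, alternative=alternative, method=method,
                         correction=(method == "approx"))
    d = cohens_d_paired(diffs) if diffs.std(ddof=1) > 0 else 0.0
    return TestResult(
        name=f"wilcoxon ({pm.measure_name})", statistic=float(res.statistic),
        df=float(n), p=float(res.pvalue), effect_size=("cohen_d", d),
        sided=sided, effect_label=effect_size_label(d),
    )


def bland_altman_plot(pm: PairedMeasures, result: Optional[AgreementResult] = None,
                      ax=None, reference_first: bool = True):
    """Scatter of pair means against wet - dry differences with dotted
    bias and limits-of-agreement lines and shaded CIs."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    result = result or bland_altman(pm, reference_first)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    means = (pm.value_wet + pm.value_dry) / 2
    diffs = pm.diffs(reference_first)
    ax.scatter(means, diffs, s=18, color="k", zorder=3)
    for y, style in [(result.bias, "-"), (result.loa_low, ":"), (result.loa_high, ":")]:
        ax.axhline(y, linestyle=style, color="gray")
    ax.axhspan(*result.bias_ci, alpha=0.15, color="tab:blue")
    ax.axhspan(*result.loa_low_ci, alpha=0.10, color="tab:orange")
    ax.axhspan(*result.loa_high_ci, alpha=0.10, color="tab:orange")
    ax.set_xlabel(f"mean of systems ({pm.units})" if pm.units else "mean of systems")
    ax.set_ylabel(f"difference {result.sign_convention}")
    ax.set_title(pm.measure_name)
    return ax


def agreement_table(measures: List[PairedMeasures]) -> pd.DataFrame:
    """Tidy agreement summary, one row per measure."""
    rows = []
    for pm in measures:
        r = bland_altman(pm)
        d = cohens_d_paired(pm.diffs()) if pm.diffs().std(ddof=1) > 0 else 0.0
        rows.append(dict(
            measure=pm.measure_name, units=pm.units, n=r.n, bias=r.bias,
            ci_lo=r.bias_ci[0], ci_hi=r.bias_ci[1],
            loa_lo=r.loa_low, loa_hi=r.loa_high, sd_diff=r.sd_diff,
            cohen_d=d, label=effect_size_label(d),
            significant=r.bias_significant,
        ))
    return pd.DataFrame(rows)
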