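"""Classical repeated-measures tests with advisory assumption checks.

Dispatches paired t (2 levels) or one-way repeated-measures ANOVA
(>= 3 levels), switching to the Wilcoxon signed-rank / Friedman
nonparametric counterparts when a Shapiro-Wilk normality screen fails.
Mauchly's sphericity test is reported as advisory metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "paired_t",
    "one_sample_t",
    "rm_anova",
    "wilcoxon_signed_rank",
    "friedman",
    "mauchly",
    "paired_tests",
]

NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must be in [0, 1]")


def paired_t(x, y) -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be equal-length vectors")
    if len(x) < 2:
        raise ValueError("need at least 2 subjects")
    d = x - y
    if np.allclose(d, 0):
        return TestResult("paired t-test", 0.0, float(len(d) - 1), 1.0)
    res = stats.ttest_rel(x, y)
    return TestResult("paired t-test", float(res.statistic), float(len(x) - 1), float(res.pvalue))


def one_sample_t(x, popmean: float = 0.0) -> TestResult:
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 subjects")
    res = stats.ttest_1samp(x, popmean)
    return TestResult(
        "one-sample t-test", float(res.statistic), float(len(x) - 1), float(res.pvalue)
    )


def rm_anova(wide: pd.DataFrame | np.ndarray) -> TestResult:
    """One-way repeated-measures ANOVA from a subjects x levels table.

    Sums-of-squares partition: total = subjects + conditions + error.
    """
    X = np.asarray(wide, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected subjects x levels table")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels")
    grand = X.mean()
    ss_total = ((X - grand) ** 2).sum()
    ss_subj = k * ((X.mean(axis=1) - grand) ** 2).sum()
    ss_cond = n * ((X.mean(axis=0) - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_cond
    df_cond = k - 1
    df_err = (n - 1) * (k - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err <= 0:
        return TestResult("rm-anova", np.inf if ms_cond > 0 else 0.0, (df_cond, df_err), 0.0 if ms_cond > 0 else 1.0)
    F = ms_cond / ms_err
    p = float(stats.f.sf(F, df_cond, df_err))
    return TestResult("rm-anova", float(F), (float(df_cond), float(df_err)), p)


def wilcoxon_signed_rank(x, y=None) -> TestResult:
    """Wilcoxon signed-rank test with continuity correction (against a
    paired sample or zero)."""
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if np.allclose(d, 0):
        return TestResult("wilcoxon signed-rank", 0.0, None, 1.0)
    res = stats.wilcoxon(d, correction=True)
    return TestResult("wilcoxon signed-rank", float(res.statistic), None, float(res.pvalue))


def friedman(wide: pd.DataFrame | np.ndarray) -> TestResult:
    X = np.asarray(wide, dtype=float)
    if X.shape[1] < 3:
        raise ValueError("Friedman's test needs >= 3 levels")
    res = stats.friedmanchisquare(*[X[:, j] for j in range(X.shape[1])])
    return TestResult(
        "friedman", float(res.statistic), float(X.shape[1] - 1), float(res.pvalue)
    )


def mauchly(wide: pd.DataFrame | np.ndarray) -> TestResult:
    """Mauchly's test of sphericity (advisory)."""
    X = np.asarray(wide, dtype=float)
    n, k = X.shape
    if k < 3:
        return TestResult("mauchly", 1.0, 0.0, 1.0, {"note": "trivial for k < 3"})
    # orthonormal contrasts of the k levels
    C = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1]
    S = np.cov(X, rowvar=False, ddof=1)
    T = C.T @ S @ C
    d = k - 1
    eig = np.linalg.eigvalsh(T)
    eig = np.clip(eig, 1e-300, None)
    W = float(np.exp(np.log(eig).sum() - d * np.log(eig.mean())))
    f = 1.0 - (2 * d * d + d + 2) / (6.0 * d * (n - 1))
    chi2 = -f * (n - 1) * np.log(max(W, 1e-300))
    df = d * (d + 1) / 2 - 1
    p = float(stats.chi2.sf(chi2, df))
    return TestResult("mauchly", W, float(df), p, {"chi2": float(chi2)})


def _pivot(table: pd.DataFrame, dv: str, within: str, subject: str) -> pd.DataFrame:
    agg = table.groupby([subject, within], sort=True)[dv].mean().reset_index()
    wide = agg.pivot(index=subject, columns=within, values=dv)
    if wide.isna().any().any():
        wide = wide.dropna()  # listwise handling of incomplete subjects
    if len(wide) < 2:
        raise ValueError("need at least 2 subjects with complete data")
    return wide


def paired_tests(
    table: pd.DataFrame,
    dv: str = "difference_score",
    within: str = "condition",
    subject: str = "subject",
    kind: str = "auto",
) -> TestResult:
    """Within-subject comparison of ``dv`` across levels of ``within``.

    ``kind='auto'`` screens each level with Shapiro-Wilk and switches to
    the nonparametric counterpart on violation; ``'parametric'`` /
    ``'nonparametric'`` force the choice.  Screening results and
    Mauchly's test ride along in ``extra``.
    """
    if kind not in ("auto", "parametric", "nonparametric"):
        raise ValueError(f"unknown kind {kind!r}")
    wide = _pivot(table, dv, within, subject)
    k = wide.shape[1]
    screening: dict[str, float] = {}
    normal = True
    if len(wide) >= 3:
        for level in wide.columns:
            stat_p = stats.shapiro(wide[level]).pvalue
            screening[f"shapiro_p[{level}]"] = float(stat_p)
            normal = normal and stat_p >= NORMALITY_ALPHA

    use_parametric = kind == "parametric" or (kind == "auto" and normal)
    if k == 2:
        a, b = wide.columns
        result = (
            paired_t(wide[a], wide[b]) if use_parametric else wilcoxon_signed_rank(wide[a], wide[b])
        )
    else:
        sph = mauchly(wide)
        screening["mauchly_p"] = sph.p_value
        result = rm_anova(wide) if use_parametric else friedman(wide)
    return TestResult(
        result.name,
        result.statistic,
        result.df,
        result.p_value,
        {**result.extra, **screening, "levels": list(map(str, wide.columns))},
    )
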