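"""Group statistics for regional white-matter metrics and study endpoints.

Covers everything the study design needs: regional ROI means, Student and
Welch t-tests, the Benjamini-Krieger-Yekutieli two-stage adaptive FDR
procedure at q = 0.1, Fisher's exact test for the tooth-eruption table,
two-way ANOVA (treatment x age) with Tukey's post-hoc comparisons, and
Pearson correlation.

The BKY procedure is the two-stage linear step-up: stage 1 runs
Benjamini-Hochberg at q' = q / (1 + q) to estimate the number of true
nulls, stage 2 re-runs BH at q' * m / (m - r1) where r1 is the stage-1
rejection count.  Reported q-values are the smallest nominal q at which a
test would be rejected by the full two-stage rule; because the procedure
is adaptive these can be smaller than the raw p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "CorrelationResult",
    "AnovaResult",
    "regional_means",
    "student_t",
    "welch_t",
    "bky_fdr",
    "fisher_exact_2x2",
    "two_way_anova_tukey",
    "pearson_correlation",
]

#: canonical white-matter region labels used in the regional analysis
WM_REGIONS = ("fmi", "gcc", "bcc", "scc", "fmj", "ec", "aca", "ic", "opt", "cp")

METRICS = ("FA", "RD", "AD", "MD")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False

    def __iter__(self):
        return iter((self.t, self.df, self.p))

    def __getitem__(self, i):
        return (self.t, self.df, self.p, self.degenerate)[i]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float
    n: int


@dataclass
class AnovaResult:
    """Two-way ANOVA F-statistics with Tukey pairwise comparisons.

    ``effects`` maps effect name -> (F, df_num, df_den, p).  ``tukey`` is a
    table of all pairwise cell comparisons; rows comparing the two
    treatments within one age carry ``within_age = True``.
    """

    effects: dict[str, tuple[float, float, float, float]]
    tukey: pd.DataFrame


def regional_means(
    scalar_maps,
    label_mask: np.ndarray,
    labels: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Mean of each scalar metric over every labeled region.

    Bilateral structures are expected to share one integer label so left
    and right voxels pool before averaging.  Returns a long table with
    columns ``region``, ``metric``, ``value``, ``n_voxels``.

    Parameters
    ----------
    scalar_maps : ScalarMapSet
    label_mask : int array
        0 = unlabeled; positive integers name regions.
    labels : dict, optional
        label value -> region name; defaults to the labels present.
        Raises if a requested label has no voxels.
    """
    label_mask = np.asarray(label_mask)
    if label_mask.shape != scalar_maps.mask.shape:
        raise ValueError("label mask shape must match the scalar maps")
    if labels is None:
        present = np.unique(label_mask[label_mask > 0])
        labels = {int(v): str(v) for v in present}
    rows = []
    for value, name in labels.items():
        sel = (label_mask == value) & scalar_maps.mask
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"region {name!r} (label {value}) has no voxels")
        for metric in METRICS:
            rows.append(
                {
                    "region": name,
                    "metric": metric,
                    "value": float(getattr(scalar_maps, metric)[sel].mean()),
                    "n_voxels": n,
                }
            )
    return pd.DataFrame(rows)


def _t_test(a, b, equal_var: bool) -> TTestResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            df = a.size + b.size - 2 if equal_var else float(a.size - 1)
            return TTestResult(t=0.0, df=float(df), p=1.0, degenerate=True)
        raise ValueError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def student_t(group_a, group_b) -> TTestResult:
    """Two-sided Student's t-test (pooled variance)."""
    return _t_test(group_a, group_b, equal_var=True)


def welch_t(group_a, group_b) -> TTestResult:
    """Two-sided Welch's t-test (Welch-Satterthwaite degrees of freedom)."""
    return _t_test(group_a, group_b, equal_var=False)


def _bh_rejections(p: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level q."""
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = q * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    flags = np.zeros(m, dtype=bool)
    if passed.any():
        kmax = np.max(np.nonzero(passed)[0])
        flags[order[: kmax + 1]] = True
    return flags


def _tsbky_rejections(p: np.ndarray, q: float) -> np.ndarray:
    """Two-stage BKY linear step-up rejection flags at level q."""
    m = p.size
    q1 = q / (1.0 + q)
    stage1 = _bh_rejections(p, q1)
    r1 = int(stage1.sum())
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    return _bh_rejections(p, q1 * m / (m - r1))


def bky_fdr(p_values, q: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage adaptive BKY FDR procedure.

    Returns ``(q_values, discovery_flags)``.  The q-value of a test is the
    smallest nominal level at which the two-stage procedure rejects it,
    found by bisection (rejection is monotone in q).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    flags = _tsbky_rejections(p, q)
    qvals = np.empty_like(p)
    for i in range(p.size):
        lo, hi = 0.0, 1.0
        # smallest q in (0, 1) rejecting test i; 1.0 if never rejected
        if not _tsbky_rejections(p, 1.0 - 1e-12)[i]:
            qvals[i] = 1.0
            continue
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            if _tsbky_rejections(p, mid)[i]:
                hi = mid
            else:
                lo = mid
        qvals[i] = hi
    return qvals, flags


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact test p-value for a 2x2 count table.

    Uses the probability-mass rule: sum over all tables with the observed
    margins whose hypergeometric probability does not exceed the observed
    table's.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("counts must be non-negative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin in table")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def two_way_anova_tukey(
    data: pd.DataFrame,
    value: str = "value",
    treatment: str = "group",
    age: str = "pnd",
) -> AnovaResult:
    """Two-way ANOVA with treatment and age as factors, plus Tukey HSD.

    Type-II sums of squares on the (near-)balanced design; Tukey's
    studentized-range test over all treatment x age cell pairs, with the
    treatment-vs-treatment comparisons within each age flagged.

    Raises on any empty design cell (the interaction term needs >= 2
    observations per cell).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = data[[value, treatment, age]].copy()
    df.columns = ["y", "trt", "age"]
    df["trt"] = df["trt"].astype(str)
    df["age"] = df["age"].astype(str)
    counts = df.groupby(["trt", "age"]).size().unstack(fill_value=0)
    if (counts.values < 2).any():
        raise ValueError("every treatment x age cell needs >= 2 observations")

    model = smf.ols("y ~ C(trt) * C(age)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    df_den = float(table.loc["Residual", "df"])
    effects = {}
    for row, name in (("C(trt)", "treatment"), ("C(age)", "age"),
                      ("C(trt):C(age)", "interaction")):
        effects[name] = (
            float(table.loc[row, "F"]),
            float(table.loc[row, "df"]),
            df_den,
            float(table.loc[row, "PR(>F)"]),
        )

    cell = df["trt"] + "@" + df["age"]
    hsd = pairwise_tukeyhsd(df["y"].to_numpy(), cell.to_numpy())
    tk = pd.DataFrame(
        hsd.summary().data[1:],
        columns=[str(c) for c in hsd.summary().data[0]],
    )
    g1 = tk["group1"].str.split("@", expand=True)
    g2 = tk["group2"].str.split("@", expand=True)
    tk["within_age"] = (g1[1] == g2[1]) & (g1[0] != g2[0])
    return AnovaResult(effects=effects, tukey=tk)


def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson correlation with two-sided p-value from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if x.var() == 0 or y.var() == 0:
        raise ValueError("constant input: correlation undefined")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(
        r=r, r_squared=r * r, p_value=float(res.pvalue), n=int(x.size)
    )
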