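"""Cohort-level statistics: normality-gated group comparisons, correlation
with a joint effect-size rule, and the multivariate diameter model.

The analysis conventions are:

* Normality is assessed per group with a Shapiro-Wilk test at alpha 0.05.
  Two normal groups are compared with a Student's t-test, otherwise with a
  Mann-Whitney U test; more than two groups use one-way ANOVA followed by
  Tukey's post-hoc test.
* A correlation is flagged significant only when p <= 0.05 **and**
  |R| > 0.25 (joint rule); Pearson's R is used when both variables pass the
  normality gate, Spearman's otherwise.
* The multivariate model regresses a dependent variable (typically the
  BSA-indexed ascending-aorta diameter) on age plus the hemodynamic
  candidates that pass the univariate joint rule and a pairwise
  collinearity screen, using ordinary least squares on z-scored variables
  so the coefficients are standardized betas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, ParameterError

__all__ = [
    "ComparisonResult",
    "CorrelationResult",
    "RegressionResult",
    "compare_groups",
    "percent_change",
    "format_percent_change",
    "correlate",
    "multivariate_model",
    "SIGNIFICANCE_ALPHA",
    "MIN_ABS_R",
]

SIGNIFICANCE_ALPHA = 0.05
MIN_ABS_R = 0.25


@dataclass
class ComparisonResult:
    parameter: str
    groups: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    ns: dict[str, int]
    test: str
    p_value: float
    percent_change: float | None = None  #: vs the reference group, unrounded
    reference: str | None = None
    normal: dict[str, bool] = field(default_factory=dict)
    posthoc: pd.DataFrame | None = None

    @property
    def significant(self) -> bool:
        return self.p_value <= SIGNIFICANCE_ALPHA


@dataclass
class CorrelationResult:
    x: str
    y: str
    method: str
    r: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        """Joint rule: p <= 0.05 and |R| > 0.25."""
        return self.p_value <= SIGNIFICANCE_ALPHA and abs(self.r) > MIN_ABS_R


@dataclass
class RegressionResult:
    dependent: str
    predictors: list[str]
    std_beta: dict[str, float]
    p_values: dict[str, float]
    overall_r: float
    dropped_univariate: list[str]
    dropped_collinear: list[str]
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": self.predictors,
                "std_beta": [self.std_beta[p] for p in self.predictors],
                "p": [self.p_values[p] for p in self.predictors],
            }
        )


def _shapiro_normal(x: np.ndarray) -> bool:
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    return sps.shapiro(x).pvalue > SIGNIFICANCE_ALPHA


def percent_change(group_value: float, reference_value: float) -> float:
    """Percent change of a group mean relative to a reference mean."""
    if reference_value == 0:
        raise ParameterError("percent change undefined for a zero reference")
    return 100.0 * (group_value - reference_value) / reference_value


def format_percent_change(pc: float) -> int:
    """Round a percent change to the integer used in report display."""
    return int(np.round(pc))


def compare_groups(
    table: pd.DataFrame,
    parameter: str,
    grouping: str,
    reference: str | None = None,
) -> ComparisonResult:
    """Compare a parameter's mean across the groups of a grouping column.

    Two groups: Shapiro-Wilk per group gates Student's t-test versus
    Mann-Whitney U. More than two: one-way ANOVA with Tukey's post-hoc.
    Groups with fewer than 3 subjects skip the normality gate and force the
    non-parametric branch.
    """
    if parameter not in table.columns or grouping not in table.columns:
        raise DataError(f"table lacks column {parameter!r} or {grouping!r}")
    clean = table[[parameter, grouping]].dropna()
    names = list(pd.unique(clean[grouping]))
    if len(names) < 2:
        raise DataError("need at least two groups to compare")
    samples = {g: clean.loc[clean[grouping] == g, parameter].to_numpy(float) for g in names}
    if any(len(v) < 2 for v in samples.values()):
        raise DataError("every group needs at least 2 subjects")

    normal = {}
    gate_ok = True
    for g, v in samples.items():
        if len(v) < 3:
            warnings.warn(f"group {g!r} has <3 subjects: normality gate skipped")
            gate_ok = False
            normal[g] = False
        else:
            normal[g] = _shapiro_normal(v)

    means = {g: float(v.mean()) for g, v in samples.items()}
    sds = {g: float(v.std(ddof=1)) for g, v in samples.items()}
    ns = {g: len(v) for g, v in samples.items()}
    posthoc = None

    if len(names) == 2:
        a, b = (samples[g] for g in names)
        if gate_ok and all(normal.values()):
            test = "t-test"
            p = float(sps.ttest_ind(a, b, equal_var=True).pvalue)
        else:
            test = "mann-whitney"
            if np.array_equal(np.sort(a), np.sort(b)):
                p = 1.0  # identical samples: no evidence of a difference
            else:
                p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    else:
        test = "anova+tukey"
        p = float(sps.f_oneway(*(samples[g] for g in names)).pvalue)
        tk = sps.tukey_hsd(*(samples[g] for g in names))
        pairs = [
            {"group_a": names[i], "group_b": names[j], "p": float(tk.pvalue[i, j])}
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]
        posthoc = pd.DataFrame(pairs)

    pc = None
    if reference is None and len(names) == 2:
        reference = names[0]
    if reference is not None and len(names) == 2:
        other = next(g for g in names if g != reference)
        if means[reference] != 0:
            pc = percent_change(means[other], means[reference])

    return ComparisonResult(
        parameter=parameter,
        groups=names,
        means=means,
        sds=sds,
        ns=ns,
        test=test,
        p_value=p,
        percent_change=pc,
        reference=reference,
        normal=normal,
        posthoc=posthoc,
    )


def correlate(table: pd.DataFrame, x: str, y: str) -> CorrelationResult:
    """Correlate two parameters with the normality-gated coefficient.

    Pearson when both variables look normal (Shapiro-Wilk), Spearman
    otherwise; the ``significant`` flag additionally requires |R| > 0.25.
    """
    clean = table[[x, y]].dropna()
    if len(clean) < 4:
        raise DataError("need at least 4 paired observations")
    xv = clean[x].to_numpy(float)
    yv = clean[y].to_numpy(float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DataError("correlation undefined for a constant variable")
    if _shapiro_normal(xv) and _shapiro_normal(yv):
        method = "pearson"
        r, p = sps.pearsonr(xv, yv)
    else:
        method = "spearman"
        r, p = sps.spearmanr(xv, yv)
    return CorrelationResult(x=x, y=y, method=method, r=float(r), p_value=float(p), n=len(clean))


def multivariate_model(
    table: pd.DataFrame,
    dependent: str,
    candidates: list[str],
    always_include: tuple[str, ...] = ("age",),
    collinearity_r: float = 0.7,
) -> RegressionResult:
    """Standardized OLS of the dependent variable on screened predictors.

    Hemodynamic candidates enter only if their univariate correlation with
    the dependent variable passes the joint rule (p <= 0.05, |R| > 0.25);
    of any candidate pair correlated above ``collinearity_r`` in absolute
    value, the one with the weaker univariate |R| is dropped. Variables in
    ``always_include`` (age by default) bypass both screens. All variables
    are z-scored, so the coefficients are standardized betas; the overall
    multiple R is reported alongside per-predictor p-values.
    """
    import statsmodels.api as sm

    cols = [dependent, *always_include, *candidates]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise DataError(f"table lacks columns {missing}")
    clean = table[list(dict.fromkeys(cols))].dropna()
    if len(clean) < 10:
        raise DataError("multivariate model needs at least 10 complete subjects")

    # univariate screen
    univ_r: dict[str, float] = {}
    kept, dropped_univ = [], []
    for c in candidates:
        if c in always_include:
            continue
        try:
            res = correlate(clean, c, dependent)
        except DataError:  # constant variable: cannot pass the screen
            dropped_univ.append(c)
            univ_r[c] = 0.0
            continue
        univ_r[c] = abs(res.r)
        (kept if res.significant else dropped_univ).append(c)

    # pairwise collinearity screen: weaker univariate |R| loses
    dropped_coll: list[str] = []
    kept_sorted = sorted(kept, key=lambda c: -univ_r[c])
    final: list[str] = []
    for c in kept_sorted:
        if any(
            abs(np.corrcoef(clean[c], clean[k])[0, 1]) > collinearity_r for k in final
        ):
            dropped_coll.append(c)
        else:
            final.append(c)

    predictors = [*always_include, *[c for c in kept if c in final]]

    def z(v):
        v = clean[v].to_numpy(float)
        sd = v.std(ddof=0)
        if sd == 0:
            return np.zeros_like(v)
        return (v - v.mean()) / sd

    ydat = z(dependent)
    X = np.column_stack([z(c) for c in predictors]) if predictors else np.empty((len(clean), 0))
    X = sm.add_constant(X, has_constant="add")
    # drop remaining exact collinearity until the design has full rank
    active = list(predictors)
    while np.linalg.matrix_rank(X) < X.shape[1] and active:
        victim = min(active, key=lambda c: univ_r.get(c, np.inf))
        warnings.warn(f"dropping {victim!r}: singular design matrix")
        dropped_coll.append(victim)
        active.remove(victim)
        X = sm.add_constant(
            np.column_stack([z(c) for c in active]) if active else np.empty((len(clean), 0)),
            has_constant="add",
        )
    predictors = active

    fit = sm.OLS(ydat, X).fit()
    betas = dict(zip(predictors, fit.params[1:]))
    pvals = dict(zip(predictors, fit.pvalues[1:]))
    if predictors and np.ptp(ydat) > 0 and np.isfinite(fit.rsquared):
        overall_r = float(np.sqrt(max(fit.rsquared, 0.0)))
    else:
        overall_r = 0.0
    return RegressionResult(
        dependent=dependent,
        predictors=predictors,
        std_beta={k: float(v) for k, v in betas.items()},
        p_values={k: float(v) for k, v in pvals.items()},
        overall_r=overall_r,
        dropped_univariate=dropped_univ,
        dropped_collinear=dropped_coll,
        n=len(clean),
    )
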