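"""Inferential layer: mixed ANOVA/ANCOVA, correlations, Welch t, normality gate.

The study design is a split-plot: a between-subjects group factor
(chronically stressed CS vs emotionally healthy EH) crossed with a
within-subjects condition factor (baseline vs open-field test, or three
levels for heart/respiratory rate).  Mixed ANOVA without a covariate is
delegated to pingouin; the mixed ANCOVA (sex covariate) is fitted by the
exact mean/difference decomposition of the two-level repeated-measures
GLM, which reproduces the SPSS-style Type III tests:

* between-subject effects (group, covariate) are OLS F-tests on the
  per-subject condition means;
* the condition main effect, group x condition interaction and
  condition x covariate term are OLS F-tests on the per-subject
  difference scores, with the group effect-coded (+-1/2) and the
  covariate centred so single-df tests are evaluated at the design
  centre.

Effect sizes are partial eta-squared for the ANOVA family and pooled-SD
Cohen's d for the t family.  No multiple-testing correction is applied
(each test at alpha = 0.05), matching the analysis plan this package
implements; treat families of tests accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .exceptions import DataError, DegenerateVarianceError, ValidationError
from .laterality import cohen_d_pooled


@dataclass(frozen=True)
class StatResult:
    """One inferential result: statistic, dfs, p, effect size."""

    effect: str
    statistic: float
    stat_name: str  # "F", "t" or "r"
    df1: Optional[float]
    df2: Optional[float]
    p: float
    effect_size: Optional[float] = None
    effect_size_name: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "effect": self.effect,
            "statistic": self.statistic,
            "stat_name": self.stat_name,
            "df1": self.df1,
            "df2": self.df2,
            "p": self.p,
            "effect_size": self.effect_size,
            "effect_size_name": self.effect_size_name,
        }


@dataclass(frozen=True)
class MixedModelResult:
    """Effects plus per-condition marginal means from a mixed fit."""

    effects: tuple[StatResult, ...]
    marginal_means: pd.DataFrame
    n_subjects: int

    def effect(self, name: str) -> StatResult:
        for e in self.effects:
            if e.effect == name:
                return e
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.to_dict() for e in self.effects])


def _partial_eta_sq(f: float, df1: float, df2: float) -> float:
    return (f * df1) / (f * df1 + df2)


def _complete_cases(
    table: pd.DataFrame, subject: str, condition: str, levels: Sequence[str]
) -> pd.DataFrame:
    """Listwise deletion: keep subjects with exactly one value per level."""
    counts = table.groupby(subject)[condition].agg(["nunique", "count"])
    ok = counts[(counts["nunique"] == len(levels)) & (counts["count"] == len(levels))]
    return table[table[subject].isin(ok.index)].copy()


def _check_cells(raw, complete, group, condition):
    """Validate the design on the raw table, subject counts on complete data."""
    cells = raw.groupby([group, condition], observed=True).size()
    groups = list(raw[group].unique())
    conditions = raw[condition].unique()
    for g in groups:
        for c in conditions:
            if (g, c) not in cells.index:
                raise DataError(f"empty design cell: group={g!r}, condition={c!r}")
    per_group = complete.groupby(group)["__subject__"].nunique()
    if set(groups) - set(per_group.index) or (per_group < 2).any():
        raise DataError("need at least 2 complete subjects per group")


def _marginal_means(table, condition, value):
    agg = table.groupby(condition, observed=True)[value].agg(["mean", "sem", "count"])
    agg = agg.reset_index().rename(
        columns={"mean": "mean", "sem": "se", "count": "n"}
    )
    return agg


def mixed_anova(
    table: pd.DataFrame,
    dv: str = "value",
    within: str = "condition",
    between: str = "group",
    subject: str = "subject_id",
) -> MixedModelResult:
    """Split-plot (mixed) ANOVA: group, condition, group x condition.

    ``table`` is long-format with one row per subject x condition level;
    subjects missing any level are dropped listwise.  Works for 2 or 3
    within-subject levels (sphericity-uncorrected, as is conventional at
    two levels and adequate for this design's reporting).
    """
    for col in (dv, within, between, subject):
        if col not in table.columns:
            raise ValidationError(f"column {col!r} missing from table")
    levels = list(pd.unique(table[within]))
    if len(levels) not in (2, 3):
        raise ValidationError("within factor must have 2 or 3 levels")
    data = _complete_cases(table, subject, within, levels)
    if data.empty:
        raise DataError("no subject has complete condition data")
    data = data.assign(__subject__=data[subject])
    _check_cells(table, data, between, within)

    if data[dv].std(ddof=1) == 0.0:
        # no variation anywhere: every effect SS is zero, report F = 0
        effects = tuple(
            StatResult(effect=name, statistic=0.0, stat_name="F", df1=None,
                       df2=None, p=1.0, effect_size=0.0,
                       effect_size_name="partial_eta_sq")
            for name in ("group", "condition", "group * condition")
        )
        return MixedModelResult(
            effects=effects,
            marginal_means=_marginal_means(data, within, dv),
            n_subjects=data[subject].nunique(),
        )

    aov = pg.mixed_anova(
        data=data, dv=dv, within=within, between=between, subject=subject
    )
    name_map = {between: "group", within: "condition", "Interaction": "group * condition"}
    effects = []
    for _, row in aov.iterrows():
        f = float(row["F"])
        df1, df2 = float(row["DF1"]), float(row["DF2"])
        effects.append(
            StatResult(
                effect=name_map.get(row["Source"], str(row["Source"])),
                statistic=f,
                stat_name="F",
                df1=df1,
                df2=df2,
                p=float(row["p_unc"]),
                effect_size=float(row["np2"]),
                effect_size_name="partial_eta_sq",
            )
        )
    return MixedModelResult(
        effects=tuple(effects),
        marginal_means=_marginal_means(data, within, dv),
        n_subjects=data[subject].nunique(),
    )


def _ols_f_tests(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-coefficient F (= t^2) tests for an OLS fit with intercept in col 0."""
    n, k = X.shape
    df2 = n - k
    if df2 < 1:
        raise DataError("not enough subjects for the ANCOVA design")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise DataError("singular ANCOVA design (collinear predictors)")
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / df2
    if sigma2 <= 0:
        raise DegenerateVarianceError("zero residual variance in ANCOVA fit")
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    f = (beta / se) ** 2
    return f, beta, df2


def mixed_ancova(
    table: pd.DataFrame,
    covariate: str = "sex",
    dv: str = "value",
    within: str = "condition",
    between: str = "group",
    subject: str = "subject_id",
) -> MixedModelResult:
    """2 x 2 mixed ANCOVA with a subject-level covariate (e.g. sex coded 0/1).

    Returns group, condition, group x condition, covariate and
    condition x covariate effects.  Restricted to two within-subject
    levels, which is exact via the mean/difference decomposition.
    """
    for col in (dv, within, between, subject, covariate):
        if col not in table.columns:
            raise ValidationError(f"column {col!r} missing from table")
    levels = list(pd.unique(table[within]))
    if len(levels) != 2:
        raise ValidationError("mixed_ancova supports exactly 2 within levels")
    data = _complete_cases(table, subject, within, levels)
    if data.empty:
        raise DataError("no subject has complete condition data")
    data = data.assign(__subject__=data[subject])
    _check_cells(table, data, between, within)

    wide = data.pivot_table(
        index=subject, columns=within, values=dv, aggfunc="first", observed=True
    )[levels]
    meta = data.drop_duplicates(subject).set_index(subject)[[between, covariate]]
    meta = meta.loc[wide.index]
    cov = pd.to_numeric(meta[covariate], errors="coerce")
    if cov.isna().any():
        raise ValidationError(f"covariate {covariate!r} must be numeric (code 0/1)")
    if cov.nunique() < 2:
        raise ValidationError(f"covariate {covariate!r} is constant")
    groups = sorted(meta[between].unique())
    if len(groups) != 2:
        raise ValidationError("between factor must have exactly 2 levels")

    # effect-coded group (+-1/2) and centred covariate: single-df tests
    # are then evaluated at the unweighted design centre (Type III)
    g = np.where(meta[between].to_numpy() == groups[1], 0.5, -0.5)
    c = (cov - cov.mean()).to_numpy(dtype=float)
    m = wide.mean(axis=1).to_numpy(dtype=float)  # between-subject part
    d = (wide[levels[1]] - wide[levels[0]]).to_numpy(dtype=float)  # within part
    X = np.column_stack([np.ones_like(g), g, c])

    f_b, _, df2 = _ols_f_tests(X, m)
    f_w, _, _ = _ols_f_tests(X, d)

    def res(name, f):
        f = float(f)
        p = float(sps.f.sf(f, 1, df2))
        return StatResult(
            effect=name,
            statistic=f,
            stat_name="F",
            df1=1.0,
            df2=float(df2),
            p=p,
            effect_size=_partial_eta_sq(f, 1.0, df2),
            effect_size_name="partial_eta_sq",
        )

    effects = (
        res("group", f_b[1]),
        res("covariate", f_b[2]),
        res("condition", f_w[0]),
        res("group * condition", f_w[1]),
        res("condition * covariate", f_w[2]),
    )
    return MixedModelResult(
        effects=effects,
        marginal_means=_marginal_means(data, within, dv),
        n_subjects=wide.shape[0],
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Pearson r with two-sided p; missing pairs deleted pairwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise DataError("need at least 3 complete pairs")
    if x.std(ddof=1) == 0.0 or y.std(ddof=1) == 0.0:
        raise DegenerateVarianceError("zero variance in a correlated series")
    r, p = sps.pearsonr(x, y)
    return StatResult(
        effect="pearson",
        statistic=float(r),
        stat_name="r",
        df1=None,
        df2=float(x.size - 2),
        p=float(p),
        effect_size=float(r),
        effect_size_name="r",
    )


def correlation_matrix(wide: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson matrix (r, p) with unit diagonal, pairwise deletion."""
    cols = list(wide.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.full((len(cols), len(cols)), np.nan), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            try:
                res = pearson_correlation(wide[a], wide[b])
                r.loc[a, b] = r.loc[b, a] = res.statistic
                p.loc[a, b] = p.loc[b, a] = res.p
            except DataError:
                r.loc[a, b] = r.loc[b, a] = np.nan
    return r, p


def welch_t(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Welch's unequal-variance t-test with pooled-SD Cohen's d.

    The Welch-Satterthwaite df is computed in closed form and the p-value
    from the t distribution at that fractional df.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValidationError("both groups need n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise DegenerateVarianceError("both groups have zero variance")
    sa2, sb2 = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / math.sqrt(sa2 + sb2)
    df = (sa2 + sb2) ** 2 / (
        sa2**2 / (a.size - 1) + sb2**2 / (b.size - 1)
    )
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult(
        effect="welch_t",
        statistic=float(t),
        stat_name="t",
        df1=None,
        df2=float(df),
        p=float(p),
        effect_size=cohen_d_pooled(a, b),
        effect_size_name="cohen_d",
    )


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Rank-based fallback when the normality gate rejects parametrics."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValidationError("both groups must be non-empty")
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return StatResult(
        effect="mann_whitney",
        statistic=float(u),
        stat_name="U",
        df1=None,
        df2=None,
        p=float(p),
    )


@dataclass(frozen=True)
class GateResult:
    """Normality-gate verdict with the Shapiro-Wilk p-values behind it."""

    decision: str  # "parametric" | "log_transform" | "nonparametric"
    shapiro_p_raw: float
    shapiro_p_log: Optional[float] = None


def normality_gate(values: Sequence[float], alpha: float = 0.05) -> GateResult:
    """Shapiro-Wilk gate: parametric, log-transform, or nonparametric.

    Tests normality at ``alpha``; on rejection retries on log-transformed
    values when all are positive; a second rejection (or non-positive
    values) flags the nonparametric path.
    """
    x = np.asarray(list(values), dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValidationError("need at least 3 values")
    if x.std(ddof=1) == 0.0:
        raise DegenerateVarianceError("constant series")
    p_raw = float(sps.shapiro(x).pvalue)
    if p_raw >= alpha:
        return GateResult("parametric", p_raw)
    if (x <= 0).any():
        return GateResult("nonparametric", p_raw)
    p_log = float(sps.shapiro(np.log(x)).pvalue)
    if p_log >= alpha:
        return GateResult("log_transform", p_raw, p_log)
    return GateResult("nonparametric", p_raw, p_log)
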