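"""Cohort statistics for the ALPS-index study design.

Covers the full battery used in ROI-based glymphatic imaging cohorts:
normality gating (Kolmogorov--Smirnov), parametric/non-parametric group
contrasts with Bonferroni post hoc tests, two-way random-effects ICC
for inter-rater agreement, propensity-score matching on age and sex,
Benjamini--Hochberg FDR adjustment, Spearman correlation families,
clinical subgrouping rules, logistic discrimination with ROC/AUC,
longitudinal rates of change and covariate-adjusted standardised
regressions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

__all__ = [
    "StatResult",
    "SubgroupRules",
    "ks_normality",
    "compare_groups",
    "icc_average",
    "propensity_match",
    "bh_adjust",
    "spearman_fdr",
    "assign_subgroups",
    "logistic_discrimination",
    "rate_of_change",
    "longitudinal_regression",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class StatResult:
    """One named statistical output."""

    name: str
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    method: str
    n: int
    p_adjusted: float | None = None
    family: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[~np.isnan(arr)]


def ks_normality(values) -> StatResult:
    """One-sample KS test against Normal(sample mean, sample SD).

    The ``normal`` flag in ``extra`` is True iff p >= 0.05.
    """
    arr = _clean(values)
    if arr.size < 3:
        raise ValueError(f"need at least 3 observations, got {arr.size}")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate sample: zero variance")
    stat, p = sps.kstest(arr, "norm", args=(arr.mean(), sd))
    return StatResult(
        name="ks_normality",
        estimate=float(stat),
        ci_low=np.nan,
        ci_high=np.nan,
        p=float(p),
        method="kolmogorov-smirnov",
        n=int(arr.size),
        extra={"normal": bool(p >= ALPHA)},
    )


def compare_groups(
    table: pd.DataFrame,
    variable: str,
    grouping: str = "group",
    categorical: bool = False,
    posthoc: str = "bonferroni",
) -> list[StatResult]:
    """Omnibus group contrast plus Bonferroni-adjusted pairwise tests.

    Continuous variables pass through a normality gate (KS per group):
    if every group looks normal the parametric branch is used (ANOVA /
    t-test), otherwise Kruskal--Wallis / Mann--Whitney.  Categorical
    variables use chi-square throughout.  The gate decision is logged.
    """
    if posthoc != "bonferroni":
        raise ValueError(f"unsupported post hoc method {posthoc!r}")
    sub = table[[grouping, variable]].dropna()
    levels = sorted(sub[grouping].unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    results: list[StatResult] = []

    if categorical:
        ct = pd.crosstab(sub[grouping], sub[variable])
        chi2, p, dof, _ = sps.chi2_contingency(ct)
        results.append(
            StatResult(
                name=f"{variable}:omnibus",
                estimate=float(chi2),
                ci_low=np.nan,
                ci_high=np.nan,
                p=float(p),
                method="chi-square",
                n=int(len(sub)),
            )
        )
        pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
        m = len(pairs)
        for a, b in pairs:
            cts = pd.crosstab(
                sub.loc[sub[grouping].isin([a, b]), grouping],
                sub.loc[sub[grouping].isin([a, b]), variable],
            )
            chi2, p, dof, _ = sps.chi2_contingency(cts)
            results.append(
                StatResult(
                    name=f"{variable}:{a}_vs_{b}",
                    estimate=float(chi2),
                    ci_low=np.nan,
                    ci_high=np.nan,
                    p=float(p),
                    p_adjusted=float(min(1.0, p * m)),
                    method="chi-square",
                    n=int(cts.to_numpy().sum()),
                )
            )
        return results

    samples = {lv: _clean(sub.loc[sub[grouping] == lv, variable]) for lv in levels}
    for lv, arr in samples.items():
        if arr.size < 3:
            raise ValueError(f"group {lv!r} has fewer than 3 observations")
        if arr.std(ddof=1) == 0:
            raise ValueError(f"group {lv!r} has degenerate (zero) variance")
    normal = all(ks_normality(arr).extra["normal"] for arr in samples.values())
    logger.info("normality gate for %s: %s branch", variable, "parametric" if normal else "non-parametric")

    arrays = [samples[lv] for lv in levels]
    if len(levels) == 2:
        if normal:
            stat, p = sps.ttest_ind(*arrays)
            method = "t-test"
        else:
            stat, p = sps.mannwhitneyu(*arrays, alternative="two-sided")
            method = "mann-whitney"
    else:
        if normal:
            stat, p = sps.f_oneway(*arrays)
            method = "anova"
        else:
            stat, p = sps.kruskal(*arrays)
            method = "kruskal-wallis"
    results.append(
        StatResult(
            name=f"{variable}:omnibus",
            estimate=float(stat),
            ci_low=np.nan,
            ci_high=np.nan,
            p=float(p),
            method=method,
            n=int(len(sub)),
            extra={"normal_branch": normal},
        )
    )

    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
    m = len(pairs)
    for a, b in pairs:
        xa, xb = samples[a], samples[b]
        if normal:
            stat, p = sps.ttest_ind(xa, xb)
            method = "t-test"
        else:
            stat, p = sps.mannwhitneyu(xa, xb, alternative="two-sided")
            method = "mann-whitney"
        results.append(
            StatResult(
                name=f"{variable}:{a}_vs_{b}",
                estimate=float(xa.mean() - xb.mean()),
                ci_low=np.nan,
                ci_high=np.nan,
                p=float(p),
                p_adjusted=float(min(1.0, p * m)),
                method=method,
                n=int(xa.size + xb.size),
            )
        )
    return results


def icc_average(ratings, model: str = "icc2k", alpha: float = 0.05) -> StatResult:
    """Average-measures intraclass correlation for a subjects x raters table.

    ``icc2k`` (default) is the two-way random-effects, absolute-agreement,
    average-measures coefficient; ``icc3k`` the two-way mixed, consistency
    variant.  The confidence interval follows the F-based construction of
    the classical ANOVA decomposition.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("ratings must be an (n_subjects, 2) array")
    if np.isnan(x).any():
        raise ValueError("missing ratings are not supported")
    n, k = x.shape
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if model not in ("icc2k", "icc3k"):
        raise ValueError(f"unknown ICC model {model!r}")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    if model == "icc3k":
        icc = (msr - mse) / msr if msr > 0 else np.nan
        f_stat = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        p = sps.f.sf(f_stat, df1, df2)
        fl = f_stat / sps.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_stat * sps.f.ppf(1 - alpha / 2, df2, df1)
        lo, hi = 1 - 1 / fl, 1 - 1 / fu
        return StatResult(
            name="icc", estimate=float(icc), ci_low=float(lo), ci_high=float(hi),
            p=float(p), method="ICC(3,k)", n=n,
        )

    # ICC(2,1) point estimate, then Spearman-Brown to average measures
    denom_single = msr + (k - 1) * mse + k * (msc - mse) / n
    icc21 = (msr - mse) / denom_single if denom_single > 0 else np.nan
    icc2k = (msr - mse) / (msr + (msc - mse) / n)

    if mse <= 0:  # perfect agreement: the F ratio degenerates
        return StatResult(
            name="icc", estimate=float(icc2k), ci_low=float(icc2k),
            ci_high=float(icc2k), p=0.0, method="ICC(2,k)", n=n,
            extra={"msr": msr, "msc": msc, "mse": mse},
        )

    f_stat = msr / mse
    df1, df2 = n - 1, (n - 1) * (k - 1)
    p = sps.f.sf(f_stat, df1, df2)

    # Satterthwaite df for the single-measures bounds (McGraw & Wong)
    fj = msc / mse
    vn = (k - 1) * (n - 1) * (
        k * icc21 * fj + n * (1 + (k - 1) * icc21) - k * icc21
    ) ** 2
    vd = (n - 1) * k**2 * icc21**2 * fj**2 + (
        n * (1 + (k - 1) * icc21) - k * icc21
    ) ** 2
    v = vn / vd
    f2u = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f2l = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lo1 = n * (msr - f2u * mse) / (
        f2u * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi1 = n * (f2l * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2l * msr
    )
    # Spearman-Brown step up to average measures
    lo = k * lo1 / (1 + (k - 1) * lo1)
    hi = k * hi1 / (1 + (k - 1) * hi1)
    return StatResult(
        name="icc", estimate=float(icc2k), ci_low=float(lo), ci_high=float(hi),
        p=float(p), method="ICC(2,k)", n=n,
        extra={"msr": msr, "msc": msc, "mse": mse},
    )


def _encode_numeric(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    for c in columns:
        col = df[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.dropna().unique())
            if len(levels) > 2:
                raise ValueError(f"cannot encode multi-level column {c!r}")
            out[c] = (col == levels[-1]).astype(float)
        else:
            out[c] = col.astype(float)
    return out


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return (a.mean() - b.mean()) / pooled


def propensity_match(
    table: pd.DataFrame,
    treatment: str,
    covariates: tuple[str, ...] = ("age", "sex"),
    caliper_scale: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """1:1 greedy nearest-neighbour propensity matching without replacement.

    The propensity model is a logistic regression of the binary
    ``treatment`` column on the covariates; matching runs on the logit
    of the propensity score with a caliper of ``caliper_scale`` times
    its pooled SD.  Returns the matched rows and a balance report of
    standardised mean differences before/after matching.
    """
    df = table.dropna(subset=[treatment, *covariates]).copy()
    t = df[treatment].astype(int).to_numpy()
    if t.sum() < 10 or (1 - t).sum() < 10:
        raise ValueError("each arm needs at least 10 subjects")
    X = _encode_numeric(df, list(covariates))
    design = sm.add_constant(X.to_numpy())
    fit = sm.Logit(t, design).fit(disp=0)
    logit_ps = design @ fit.params
    caliper = caliper_scale * np.std(logit_ps, ddof=1)

    treated = np.flatnonzero(t == 1)
    control = np.flatnonzero(t == 0)
    rng = np.random.default_rng(seed)
    order = rng.permutation(treated)
    available = set(control.tolist())
    pairs: list[tuple[int, int]] = []
    for ti in order:
        if not available:
            break
        cand = np.fromiter(available, dtype=int)
        d = np.abs(logit_ps[cand] - logit_ps[ti])
        j = int(np.argmin(d))
        if d[j] <= caliper:
            pairs.append((ti, int(cand[j])))
            available.discard(int(cand[j]))
    matched_idx = [i for pair in pairs for i in pair]
    matched = df.iloc[matched_idx].copy()
    matched["match_id"] = np.repeat(np.arange(len(pairs)), 2)

    rows = []
    Xm = _encode_numeric(matched, list(covariates))
    tm = matched[treatment].astype(int).to_numpy()
    for c in covariates:
        before = _smd(X[c].to_numpy()[t == 1], X[c].to_numpy()[t == 0])
        after = (
            _smd(Xm[c].to_numpy()[tm == 1], Xm[c].to_numpy()[tm == 0])
            if len(pairs)
            else np.nan
        )
        rows.append({"covariate": c, "smd_before": before, "smd_after": after})
    balance = pd.DataFrame(rows)
    logger.info("propensity matching kept %d pairs of %d treated", len(pairs), t.sum())
    return matched, balance


def bh_adjust(pvalues, family: str | None = None) -> np.ndarray:
    """Benjamini--Hochberg step-up adjusted p-values, original order.

    adj_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def spearman_fdr(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    family: str = "correlations",
) -> list[StatResult]:
    """Spearman rank correlations for each (x, y) pair, BH-adjusted
    within the declared family.  Complete cases per pair; constant
    columns are an error."""
    raw: list[StatResult] = []
    for xcol, ycol in pairs:
        sub = table[[xcol, ycol]].dropna()
        if len(sub) < 5:
            raise ValueError(f"pair ({xcol}, {ycol}) has fewer than 5 complete cases")
        x, y = sub[xcol].to_numpy(float), sub[ycol].to_numpy(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            raise ValueError(f"constant column in pair ({xcol}, {ycol})")
        rho, p = sps.spearmanr(x, y)
        raw.append(
            StatResult(
                name=f"spearman:{xcol}~{ycol}",
                estimate=float(rho),
                ci_low=np.nan,
                ci_high=np.nan,
                p=float(p),
                method="spearman",
                n=int(len(sub)),
                family=family,
            )
        )
    adj = bh_adjust([r.p for r in raw], family)
    return [
        StatResult(
            name=r.name, estimate=r.estimate, ci_low=r.ci_low, ci_high=r.ci_high,
            p=r.p, p_adjusted=float(a), family=family, method=r.method, n=r.n,
        )
        for r, a in zip(raw, adj)
    ]


@dataclass(frozen=True)
class SubgroupRules:
    """Clinical subgrouping thresholds for the PD and piRBD groups."""

    hy_early_max: float = 2.5  # H-Y <= 2.5 is early-stage PD
    mmse_normal_min: int = 27  # cognitive impairment: MMSE < 27 or MoCA < 24
    moca_normal_min: int = 24
    rbdq_total_cut: int = 17  # symptomatic RBD: total > 17 or factor II > 7
    rbdq_ii_cut: int = 7
    ess_eds_min: int = 10  # excessive daytime sleepiness: ESS >= 10


def assign_subgroups(table: pd.DataFrame, rules: SubgroupRules | None = None) -> pd.DataFrame:
    """Attach the clinical subgroup columns.

    PD rows get stage (Early/Late by H-Y), motor tercile (mild /
    intermediate / severe at the table's own UPDRS III mean +- SD),
    cognition (PD-CI / PDN), symptomatic-RBD and daytime-sleepiness
    labels; piRBD rows get the cognition analogue.  Rows with the
    required score missing keep a missing label.
    """
    rules = rules or SubgroupRules()
    df = table.copy()
    pd_rows = df["group"] == "PD"
    rbd_rows = df["group"] == "piRBD"

    def _where(mask, cond, yes, no):
        out = pd.Series(pd.NA, index=df.index, dtype="object")
        valid = mask & cond.notna()
        truth = cond[valid].astype(bool)
        out.loc[truth.index[truth]] = yes
        out.loc[truth.index[~truth]] = no
        return out

    df["stage_group"] = _where(
        pd_rows, df["hy_stage"] <= rules.hy_early_max, "Early-PD", "Late-PD"
    )

    updrs = df.loc[pd_rows, "updrs_iii"]
    mu, sd = updrs.mean(), updrs.std(ddof=1)
    motor = pd.Series(pd.NA, index=df.index, dtype="object")
    motor[pd_rows & (df["updrs_iii"] < mu - sd)] = "mild"
    motor[pd_rows & (df["updrs_iii"] >= mu - sd) & (df["updrs_iii"] <= mu + sd)] = "intermediate"
    motor[pd_rows & (df["updrs_iii"] > mu + sd)] = "severe"
    df["motor_group"] = motor

    ci = (df["mmse"] < rules.mmse_normal_min) | (df["moca"] < rules.moca_normal_min)
    ci = ci.where(df["mmse"].notna() & df["moca"].notna())
    df["cognitive_group"] = _where(pd_rows, ci, "PD-CI", "PDN")
    df.loc[rbd_rows, "cognitive_group"] = _where(rbd_rows, ci, "piRBD-CI", "piRBDN")[rbd_rows]

    srbd = (df["rbdq_hk_total"] > rules.rbdq_total_cut) | (df["rbdq_hk_ii"] > rules.rbdq_ii_cut)
    srbd = srbd.where(df["rbdq_hk_total"].notna() & df["rbdq_hk_ii"].notna())
    df["rbd_group"] = _where(pd_rows, srbd, "PD-sRBD", "PD-nRBD")

    df["eds_group"] = _where(pd_rows, df["ess"] >= rules.ess_eds_min, "PD-EDS", "PD-NEDS")
    return df


def logistic_discrimination(
    table: pd.DataFrame,
    predictors: tuple[str, ...] = ("age", "sex", "moca", "hamd", "alps_index"),
    outcome: str | None = None,
    positive_group: str = "PD",
) -> tuple[list[StatResult], dict]:
    """Multivariable logistic discrimination of PD with per-predictor
    odds ratios and an in-sample ROC curve.

    By default the outcome codes PD = 1 against everyone else.  A
    separation guard aborts when the likelihood maximiser diverges
    (coefficients running away or non-convergence).
    """
    df = table.dropna(subset=[*predictors] + ([outcome] if outcome else ["group"])).copy()
    if outcome:
        y = df[outcome].astype(int).to_numpy()
    else:
        y = (df["group"] == positive_group).astype(int).to_numpy()
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both outcome classes must be present")
    X = _encode_numeric(df, list(predictors))
    design = sm.add_constant(X.to_numpy())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # divergence is handled below
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise ValueError(f"separation guard: logistic fit failed ({exc})") from exc
    if (not fit.mle_retvals.get("converged", True)) or np.max(np.abs(fit.params)) > 1e3:
        raise ValueError("separation guard: coefficient divergence detected")

    conf = fit.conf_int()
    results = []
    for i, name in enumerate(predictors, start=1):
        results.append(
            StatResult(
                name=f"or:{name}",
                estimate=float(np.exp(fit.params[i])),
                ci_low=float(np.exp(conf[i, 0])),
                ci_high=float(np.exp(conf[i, 1])),
                p=float(fit.pvalues[i]),
                method="logistic-wald",
                n=int(y.size),
                extra={"coef": float(fit.params[i])},
            )
        )
    scores = fit.predict(design)
    fpr, tpr, _ = roc_curve(y, scores)
    roc = {"fpr": fpr, "tpr": tpr, "auc": float(_trapezoid_auc(fpr, tpr))}
    return results, roc


def rate_of_change(baseline, follow_up, interval_months):
    """Rate of change: (follow-up - baseline) / interval * 100, in
    percent of the raw scale per month.  Exactly antisymmetric in its
    first two arguments."""
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(follow_up, dtype=float)
    t = np.asarray(interval_months, dtype=float)
    if np.any(t <= 0):
        raise ValueError("follow-up interval must be positive")
    out = (f - b) / t * 100.0
    if out.ndim == 0:
        return float(out)
    return out


def longitudinal_regression(
    table: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: tuple[str, ...] = ("age", "sex"),
    family: str | None = None,
) -> StatResult:
    """OLS of a z-standardised outcome on a z-standardised predictor
    with covariates (continuous covariates standardised, binary encoded
    0/1).  Reports the standardised coefficient of the predictor; the
    raw-scale coefficient is kept in ``extra``."""
    cols = [outcome, predictor, *covariates]
    df = table.dropna(subset=cols).copy()
    n = len(df)
    if n <= len(covariates) + 3:
        raise ValueError("too few complete cases for the requested model")

    def z(v: pd.Series) -> pd.Series:
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"constant column {v.name!r}")
        return (v - v.mean()) / sd

    enc = _encode_numeric(df, cols)
    y_raw = enc[outcome]
    x_raw = enc[predictor]
    parts = [z(x_raw).rename(predictor)]
    for c in covariates:
        col = enc[c]
        std = z(col) if col.nunique() > 2 else col
        parts.append(std.rename(c))
    X = pd.concat(parts, axis=1)
    design = sm.add_constant(X.to_numpy())
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design: collinear covariates")
    fit = sm.OLS(z(y_raw).to_numpy(), design).fit()
    conf = fit.conf_int()
    raw_fit = sm.OLS(y_raw.to_numpy(), sm.add_constant(
        pd.concat([x_raw] + [enc[c] for c in covariates], axis=1).to_numpy()
    )).fit()
    return StatResult(
        name=f"B:{outcome}~{predictor}",
        estimate=float(fit.params[1]),
        ci_low=float(conf[1, 0]),
        ci_high=float(conf[1, 1]),
        p=float(fit.pvalues[1]),
        method="ols-standardised",
        n=n,
        family=family,
        extra={"coef_raw": float(raw_fit.params[1])},
    )
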