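"""Synthetic cohort generator for a three-group glymphatic imaging study.

Produces subject-level tables for healthy controls (HC), possible
idiopathic REM-sleep-behaviour-disorder patients (piRBD) and Parkinson's
disease patients (PD), with per-group means/SDs and binary frequencies
matching a published baseline-characteristics table, plus a paired
longitudinal table for the PD follow-up arm.

Continuous variables are drawn through a Gaussian copula so that
designated ALPS--severity associations can be induced without
distorting the marginal means and SDs; scores are then truncated to
their instrument ranges and rounded where the instrument is
integer-valued.  Because reported associations are Spearman
correlations, copula entries are specified as target Spearman rho and
converted to the latent Pearson rho via rho = 2 sin(pi * rho_s / 6).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "CohortSpec",
    "LongitudinalSpec",
    "default_cohort_spec",
    "generate_cohort",
    "generate_longitudinal",
    "spearman_to_pearson",
]

GROUPS = ("HC", "piRBD", "PD")

# variable -> (kind, lower, upper); kind in {continuous, integer, halfstep}
VARIABLE_KINDS: dict[str, tuple[str, float, float]] = {
    "age": ("continuous", 18.0, 95.0),
    "education": ("integer", 0.0, 25.0),
    "mmse": ("integer", 0.0, 30.0),
    "moca": ("integer", 0.0, 30.0),
    "hamd": ("integer", 0.0, 52.0),
    "hama": ("integer", 0.0, 56.0),
    "rbdq_hk_total": ("integer", 0.0, 100.0),
    "rbdq_hk_ii": ("integer", 0.0, 70.0),
    "ess": ("integer", 0.0, 24.0),
    "pdss": ("continuous", 0.0, 150.0),
    "updrs_iii": ("integer", 0.0, 132.0),
    "hy_stage": ("halfstep", 0.0, 5.0),
    "led": ("continuous", 0.0, np.inf),
    "disease_duration": ("continuous", 0.0, np.inf),
    "alps_index": ("continuous", 0.05, np.inf),
}

BINARY_VARIABLES = ("smoking", "hypertension", "hyperlipidaemia", "hyperglycaemia")

# (mean, sd) per group; None where the instrument was not administered.
_TABLE_CONTINUOUS: dict[str, dict[str, tuple[float, float] | None]] = {
    "age": {"HC": (61.96, 7.21), "piRBD": (61.90, 7.57), "PD": (59.85, 9.88)},
    "education": {"HC": (9.63, 3.63), "piRBD": (6.36, 3.86), "PD": (8.31, 4.71)},
    "mmse": {"HC": (28.26, 1.80), "piRBD": (25.61, 4.12), "PD": (26.80, 3.83)},
    "moca": {"HC": (24.54, 3.61), "piRBD": (20.21, 5.31), "PD": (22.08, 5.59)},
    "hamd": {"HC": (2.43, 2.89), "piRBD": (6.26, 5.11), "PD": (6.06, 5.14)},
    "hama": {"HC": (2.88, 3.55), "piRBD": (7.22, 5.80), "PD": (5.50, 4.80)},
    "rbdq_hk_total": {"HC": (8.46, 6.25), "piRBD": (33.08, 12.21), "PD": (16.47, 13.34)},
    "rbdq_hk_ii": {"HC": (1.99, 3.15), "piRBD": (18.24, 10.06), "PD": (8.02, 9.45)},
    "ess": {"HC": (6.13, 4.74), "piRBD": None, "PD": (5.93, 5.07)},
    "pdss": {"HC": (129.54, 17.29), "piRBD": None, "PD": (125.64, 20.64)},
    "updrs_iii": {"HC": (0.58, 1.26), "piRBD": (5.36, 7.49), "PD": (21.64, 12.37)},
    "hy_stage": {"HC": None, "piRBD": None, "PD": (2.34, 0.50)},
    "led": {"HC": None, "piRBD": None, "PD": (305.70, 286.60)},
    "disease_duration": {"HC": None, "piRBD": None, "PD": (3.50, 2.99)},
    "alps_index": {"HC": (1.31, 0.17), "piRBD": (1.25, 0.17), "PD": (1.20, 0.17)},
}

# positive-case frequencies (first number of the printed a/b pairs)
_TABLE_BINARY: dict[str, dict[str, float]] = {
    "female": {"HC": 70 / 129, "piRBD": 57 / 119, "PD": 72 / 168},
    "smoking": {"HC": 32 / 129, "piRBD": 51 / 119, "PD": 40 / 168},
    "hypertension": {"HC": 45 / 129, "piRBD": 48 / 119, "PD": 42 / 168},
    "hyperlipidaemia": {"HC": 18 / 129, "piRBD": 8 / 119, "PD": 7 / 168},
    "hyperglycaemia": {"HC": 7 / 129, "piRBD": 12 / 119, "PD": 20 / 168},
}


def spearman_to_pearson(rho_s: float) -> float:
    """Latent Gaussian-copula correlation reproducing a target Spearman rho."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


@dataclass(frozen=True)
class LongitudinalSpec:
    """Paired baseline/follow-up marginals for the PD follow-up arm.

    ``marginals`` maps a variable to (mean_baseline, sd_baseline,
    mean_followup, sd_followup); ``retest_correlation`` is the latent
    baseline--follow-up correlation shared across scored variables.
    Age and disease duration advance deterministically with the
    follow-up interval; chronic history flags are drawn once.
    The follow-up interval is a truncated normal (lower bound at the
    12-month eligibility floor) whose location is calibrated so the
    post-truncation mean equals the requested mean.
    """

    n_pairs: int = 50
    interval_mean: float = 23.36
    interval_sd: float = 13.23
    interval_min: float = 12.0
    retest_correlation: float = 0.7
    marginals: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "mmse": (27.20, 3.57, 27.14, 3.04),
            "moca": (22.68, 5.34, 22.44, 4.98),
            "hamd": (6.22, 4.58, 6.60, 0.04),
            "hama": (5.52, 4.15, 7.12, 5.23),
            "ess": (5.78, 4.73, 6.64, 5.07),
            "pdss": (127.42, 21.81, 121.38, 19.68),
            "updrs_iii": (22.96, 13.67, 20.98, 13.36),
            "hy_stage": (2.34, 0.50, 2.17, 0.50),
            "led": (305.70, 286.60, 543.58, 313.97),
            "alps_index": (1.20, 0.17, 1.20, 0.17),
        }
    )
    baseline_age: tuple[float, float] = (60.27, 8.16)
    baseline_duration: tuple[float, float] = (3.50, 2.99)
    binary_freq: dict[str, float] = field(
        default_factory=lambda: {
            "smoking": 13 / 50,
            "hypertension": 19 / 50,
            "hyperlipidaemia": 3 / 50,
            "hyperglycaemia": 8 / 50,
        }
    )


@dataclass(frozen=True)
class CohortSpec:
    """Everything the generator needs: group sizes, marginals, copula
    entries and the longitudinal block."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"HC": 129, "piRBD": 119, "PD": 168}
    )
    continuous: dict[str, dict[str, tuple[float, float] | None]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _TABLE_CONTINUOUS.items()}
    )
    binary: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _TABLE_BINARY.items()}
    )
    # (group, var_a, var_b, target Spearman rho)
    correlations: tuple[tuple[str, str, str, float], ...] = (
        # reported ALPS--severity association in the prodromal group
        ("piRBD", "alps_index", "rbdq_hk_ii", -0.236),
        # ALPS--motor-severity association carried by the PD subgroups
        ("PD", "alps_index", "updrs_iii", -0.303),
        # intra-instrument consistency (factor II is part of the total)
        ("HC", "rbdq_hk_total", "rbdq_hk_ii", 0.8),
        ("piRBD", "rbdq_hk_total", "rbdq_hk_ii", 0.8),
        ("PD", "rbdq_hk_total", "rbdq_hk_ii", 0.8),
        ("HC", "mmse", "moca", 0.7),
        ("piRBD", "mmse", "moca", 0.7),
        ("PD", "mmse", "moca", 0.7),
    )
    n_pd_with_rbdq: int = 88  # RBDQ-HK was administered to a PD subset
    longitudinal: LongitudinalSpec = field(default_factory=LongitudinalSpec)

    def replace(self, **kw) -> "CohortSpec":
        return dataclasses.replace(self, **kw)


def default_cohort_spec() -> CohortSpec:
    return CohortSpec()


def _truncate_round(values: np.ndarray, var: str) -> np.ndarray:
    kind, lo, hi = VARIABLE_KINDS[var]
    values = np.clip(values, lo, hi)
    if kind == "integer":
        values = np.round(values)
    elif kind == "halfstep":
        values = np.round(values * 2.0) / 2.0
    return values


def _group_copula(
    spec: CohortSpec, group: str, variables: list[str]
) -> np.ndarray:
    k = len(variables)
    corr = np.eye(k)
    idx = {v: i for i, v in enumerate(variables)}
    for g, a, b, rho_s in spec.correlations:
        if g != group or a not in idx or b not in idx:
            continue
        r = spearman_to_pearson(rho_s)
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise ValueError(f"copula correlation matrix for {group} is not PSD")
    return corr


def generate_cohort(spec: CohortSpec | None = None, seed: int = 0) -> pd.DataFrame:
    """Draw one cross-sectional cohort.

    Returns a tidy table with one row per subject.  Instruments not
    administered in a group (ESS/PDSS in piRBD; staging, medication and
    duration outside PD) are NaN; the RBDQ-HK scales are present for a
    random subset of PD patients of the configured size.
    """
    spec = spec or default_cohort_spec()
    rng = np.random.default_rng(seed)
    frames = []
    for group in GROUPS:
        n = spec.group_sizes[group]
        present = [v for v in VARIABLE_KINDS if spec.continuous[v].get(group) is not None]
        corr = _group_copula(spec, group, present)
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(present)))
        z = rng.standard_normal((n, len(present))) @ chol.T
        cols: dict[str, np.ndarray] = {}
        for j, var in enumerate(present):
            mean, sd = spec.continuous[var][group]
            if sd == 0:
                cols[var] = np.full(n, mean)
            else:
                cols[var] = _truncate_round(mean + sd * z[:, j], var)
        for var in VARIABLE_KINDS:
            if var not in cols:
                cols[var] = np.full(n, np.nan)
        sex_p = spec.binary["female"][group]
        cols["sex"] = np.where(rng.random(n) < sex_p, "F", "M")
        for var in BINARY_VARIABLES:
            cols[var] = (rng.random(n) < spec.binary[var][group]).astype(int)
        df = pd.DataFrame(cols)
        df.insert(0, "group", group)
        df.insert(0, "subject_id", [f"{group}-{i:03d}" for i in range(n)])
        if group == "PD" and spec.n_pd_with_rbdq < n:
            drop = rng.choice(n, size=n - spec.n_pd_with_rbdq, replace=False)
            df.loc[drop, ["rbdq_hk_total", "rbdq_hk_ii"]] = np.nan
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _calibrated_interval_loc(lspec: LongitudinalSpec) -> float:
    """Location of the truncated normal whose post-truncation mean equals
    the reported follow-up interval mean."""

    def gap(loc: float) -> float:
        a = (lspec.interval_min - loc) / lspec.interval_sd
        return (
            sps.truncnorm.mean(a, np.inf, loc=loc, scale=lspec.interval_sd)
            - lspec.interval_mean
        )

    return optimize.brentq(gap, lspec.interval_mean - 60.0, lspec.interval_mean + 10.0)


def generate_longitudinal(spec: CohortSpec | None = None, seed: int = 0) -> pd.DataFrame:
    """Draw the paired baseline/follow-up PD table.

    Follow-up scores are correlated redraws: with baseline z-score z_b,
    the follow-up value is mean_f + sd_f * (rho z_b + sqrt(1-rho^2) e).
    A retest correlation below 1 therefore builds regression to the
    mean into the rates of change, as in any real repeated measure.
    """
    spec = spec or default_cohort_spec()
    lspec = spec.longitudinal
    rng = np.random.default_rng(seed)
    n = lspec.n_pairs
    rho = lspec.retest_correlation

    loc = _calibrated_interval_loc(lspec)
    a = (lspec.interval_min - loc) / lspec.interval_sd
    interval = sps.truncnorm.rvs(
        a, np.inf, loc=loc, scale=lspec.interval_sd, size=n, random_state=rng
    )

    cols: dict[str, np.ndarray] = {"interval_months": interval}
    mean_a, sd_a = lspec.baseline_age
    age_b = np.clip(mean_a + sd_a * rng.standard_normal(n), 18.0, 95.0)
    cols["age"] = age_b
    cols["age_fu"] = age_b + interval / 12.0
    mean_d, sd_d = lspec.baseline_duration
    dur_b = np.clip(mean_d + sd_d * rng.standard_normal(n), 0.0, None)
    cols["disease_duration"] = dur_b
    cols["disease_duration_fu"] = dur_b + interval / 12.0

    for var, (mb, sb, mf, sf) in lspec.marginals.items():
        z_b = rng.standard_normal(n)
        z_f = rho * z_b + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)
        cols[var] = _truncate_round(mb + sb * z_b, var)
        cols[f"{var}_fu"] = _truncate_round(mf + sf * z_f, var)

    cols["sex"] = np.where(rng.random(n) < 72 / 168, "F", "M")  # PD-group sex ratio
    for var, p in lspec.binary_freq.items():
        cols[var] = (rng.random(n) < p).astype(int)

    df = pd.DataFrame(cols)
    df.insert(0, "subject_id", [f"PDL-{i:03d}" for i in range(n)])
    return df
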