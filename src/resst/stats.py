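"""Classical inference layer: repeated-measures ANOVA, Tukey-Kramer
post-hoc tests, Pearson correlation, Friedman test, per-subject first-level
tests, and the partial-eta-squared -> Cohen's f conversion.

The repeated-measures ANOVA is the textbook two-way (subjects x conditions)
decomposition without sphericity correction, matching the uncorrected
df = (k-1, (k-1)(n-1)) convention; a Greenhouse-Geisser correction is
available behind a flag.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "EffectSize",
    "PosthocResult",
    "CorrResult",
    "FriedmanResult",
    "rm_anova",
    "eta2_to_f",
    "tukey_kramer",
    "pearson",
    "friedman",
    "first_level_ttests",
]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_effect: float
    df_error: float
    p_value: float
    eta2p: float
    ms_error: float
    gg_epsilon: float | None = None


@dataclass(frozen=True)
class EffectSize:
    eta2p: float
    cohen_f: float


@dataclass(frozen=True)
class PosthocResult:
    comparisons: list  # of dicts: {a, b, mean_diff, q, p_adj}


@dataclass(frozen=True)
class CorrResult:
    r: float
    p_value: float
    n: int
    defined: bool = True


@dataclass(frozen=True)
class FriedmanResult:
    chi2: float
    df: int
    p_value: float


def _as_matrix(matrix):
    m = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    if m.ndim != 2:
        raise ValueError("expected a subjects x conditions matrix")
    if np.isnan(m).any():
        raise ValueError("matrix has missing cells")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    return m


def rm_anova(matrix, gg_correction: bool = False) -> AnovaResult:
    """One-way repeated-measures ANOVA on a subjects x conditions matrix.

    Subject effects are removed by the two-way decomposition
    SS_total = SS_subjects + SS_conditions + SS_error;
    F = MS_cond / MS_error with df (k-1, (k-1)(n-1)), and the effect size
    is partial eta squared = SS_cond / (SS_cond + SS_error).
    """
    m = _as_matrix(matrix)
    n, k = m.shape
    grand = m.mean()
    ss_subj = k * ((m.mean(axis=1) - grand) ** 2).sum()
    ss_cond = n * ((m.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((m - grand) ** 2).sum()
    ss_err = ss_tot - ss_subj - ss_cond
    df_e, df_r = k - 1.0, (k - 1.0) * (n - 1.0)
    ms_cond = ss_cond / df_e
    ms_err = ss_err / df_r
    if ms_err <= 0:  # constant-per-subject matrix: no error variance
        f = 0.0 if ss_cond <= 1e-300 else float("inf")
    else:
        f = ms_cond / ms_err
    eps = None
    if gg_correction:
        # Greenhouse-Geisser epsilon from the double-centered covariance
        c = np.cov(m, rowvar=False, ddof=1)
        cc = c - c.mean(axis=0) - c.mean(axis=1)[:, None] + c.mean()
        eps = float(np.trace(cc) ** 2 / ((k - 1) * (cc ** 2).sum()))
        df_e, df_r = df_e * eps, df_r * eps
    p = float(sps.f.sf(f, df_e, df_r)) if math.isfinite(f) else 0.0
    if f == 0.0 and ss_cond <= 1e-300:
        p = 1.0
    denom = ss_cond + ss_err
    eta2p = float(ss_cond / denom) if denom > 0 else 0.0
    return AnovaResult(
        F=float(f),
        df_effect=df_e,
        df_error=df_r,
        p_value=p,
        eta2p=eta2p,
        ms_error=float(ms_err),
        gg_epsilon=eps,
    )


def eta2_to_f(eta2p: float) -> float:
    """Cohen's f from partial eta squared: f = sqrt(eta2p / (1 - eta2p))."""
    if not (0.0 <= eta2p < 1.0):
        raise ValueError("eta2p must be in [0, 1)")
    return math.sqrt(eta2p / (1.0 - eta2p))


def tukey_kramer(matrix) -> PosthocResult:
    """Tukey-Kramer pairwise comparisons after a repeated-measures ANOVA.

    Uses the studentized range with MS_error and df_error from the
    within-subject decomposition: q = |mean_a - mean_b| / sqrt(MS_error/n).
    """
    m = _as_matrix(matrix)
    n, k = m.shape
    res = rm_anova(m)
    labels = (
        list(matrix.columns) if isinstance(matrix, pd.DataFrame) else list(range(k))
    )
    means = m.mean(axis=0)
    se = math.sqrt(res.ms_error / n) if res.ms_error > 0 else 0.0
    comps = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            if se > 0:
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, res.df_error))
            else:
                q, p = 0.0, 1.0
            if diff == 0:
                q, p = 0.0, 1.0
            comps.append(
                {"a": labels[i], "b": labels[j], "mean_diff": float(diff),
                 "q": float(q), "p_adj": min(p, 1.0)}
            )
    return PosthocResult(comparisons=comps)


def pearson(x, y) -> CorrResult:
    """Pearson correlation; flagged undefined under zero variance."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrResult(r=float("nan"), p_value=float("nan"), n=x.size, defined=False)
    r, p = sps.pearsonr(x, y)
    return CorrResult(r=float(r), p_value=float(p), n=x.size)


def friedman(matrix) -> FriedmanResult:
    """Friedman rank test across the condition columns."""
    m = _as_matrix(matrix)
    if np.allclose(m, m[:, [0]]):
        return FriedmanResult(chi2=0.0, df=m.shape[1] - 1, p_value=1.0)
    chi2, p = sps.friedmanchisquare(*m.T)
    return FriedmanResult(chi2=float(chi2), df=m.shape[1] - 1, p_value=float(p))


def first_level_ttests(
    trials: pd.DataFrame,
    pair,
    alpha: float = 0.05,
    variable: str = "rt_ms",
    phase: str = "test",
) -> pd.DataFrame:
    """Within-subject first-level test between two cue conditions.

    For each subject, a Welch two-sample t-test compares the trial-level
    values (go-trial RTs by default) between the two conditions; trial
    counts differ between conditions, so the trial-wise samples cannot be
    literally paired.  Returns one row per subject with t, p and the
    significance decision at ``alpha``.
    """
    cond_a, cond_b = pair
    data = trials[(trials["phase"] == phase) & (trials["trial_type"] == "go")]
    rows = []
    for sid, sub in data.groupby("subject_id", observed=True):
        xa = sub.loc[sub["condition"] == cond_a, variable].dropna()
        xb = sub.loc[sub["condition"] == cond_b, variable].dropna()
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"subject {sid}: need >= 2 trials per condition")
        t, p = sps.ttest_ind(xa, xb, equal_var=False)
        rows.append(
            {"subject_id": sid, "t": float(t), "p_value": float(p),
             "significant": bool(p < alpha)}
        )
    return pd.DataFrame(rows)
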