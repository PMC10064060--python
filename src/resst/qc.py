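"""Subject screening: unimodality (Hartigan dip), race-model independence,
and the p(response) inclusion window.

The dip statistic measures the distance between the empirical CDF and the
closest unimodal CDF; it is computed exactly with the greatest convex
minorant / least concave majorant algorithm.  Significance is assessed by a
Monte-Carlo bootstrap against samples from the uniform distribution, the
least-favorable unimodal null.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DipResult",
    "ScreeningReport",
    "SubjectScreening",
    "dip_statistic",
    "dip_test",
    "dip_null_table",
    "independence_check",
    "screen_cohort",
]

P_RESPOND_WINDOW = (0.35, 0.65)


# ---------------------------------------------------------------------------
# Hartigan dip statistic
# ---------------------------------------------------------------------------

def dip_statistic(sample) -> float:
    """Exact dip statistic of a one-dimensional sample.

    The dip is ``inf_G sup_x |F_n(x) - G(x)|`` over unimodal CDFs *G*
    (equivalently, half the maximum deviation between the empirical CDF and
    the closest fitting unimodal CDF).  It is invariant under affine
    increasing transforms of the data (but not under general monotone
    transforms, which can change which distributions count as unimodal)
    and bounded below by ``1/(2n)`` for samples of distinct values.

    Parameters
    ----------
    sample : array-like
        At least two finite values.

    Returns
    -------
    float
        The dip statistic, in ``[0, 0.25]``.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("dip_statistic requires a sample of size >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip_statistic requires finite values")
    if x[0] == x[-1]:
        return 0.0  # degenerate one-point distribution is unimodal

    # 1-indexed copies keep the hull book-keeping close to the published
    # algorithm; counts (1..n) serve as unscaled ECDF values.
    xs = np.concatenate(([np.nan], x))
    mn = np.zeros(n + 1, dtype=np.int64)  # GCM predecessor pointers
    mj = np.zeros(n + 1, dtype=np.int64)  # LCM successor pointers

    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or (xs[j] - xs[mnj]) * (mnj - mnmnj) < (
                xs[mnj] - xs[mnmnj]
            ) * (j - mnj):
                break
            mn[j] = mnmnj

    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n or (xs[k] - xs[mjk]) * (mjk - mjmjk) < (
                xs[mjk] - xs[mjmjk]
            ) * (k - mjk):
                break
            mj[k] = mjmjk

    low, high = 1, n
    dip = 1.0  # count units; enforces the 1/(2n) lower bound

    while True:
        # GCM change points from high down to low, LCM from low up to high.
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(int(mn[gcm[-1]]))
        l_gcm = len(gcm)
        gcm = [0] + gcm  # 1-indexed
        lcm = [low]
        while lcm[-1] < high:
            lcm.append(int(mj[lcm[-1]]))
        l_lcm = len(lcm)
        lcm = [0] + lcm

        ig = l_gcm
        ih = l_lcm
        # Largest distance between the GCM and LCM curves on [low, high].
        if l_gcm != 2 or l_lcm != 2:
            ix = l_gcm - 1
            iv = 2
            d = 0.0
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # next change point from the LCM; GCM interpolated there
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (xs[lcmiv] - xs[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (xs[gcmix] - xs[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # next change point from the GCM; LCM interpolated there
                    lcmiv1 = lcm[iv - 1]
                    dx = (xs[gcmix] - xs[lcmiv1]) * (lcmiv - lcmiv1) / (
                        xs[lcmiv] - xs[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0

        if d < dip:
            break

        # Maximum deviation of the ECDF above the GCM on [low, gcm[ig]].
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb = gcm[j + 1]
            je = gcm[j]
            if je - jb > 1 and xs[je] != xs[jb]:
                c = (je - jb) / (xs[je] - xs[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (xs[jj] - xs[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t

        # Maximum deviation of the LCM above the ECDF on [lcm[ih], high].
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb = lcm[j]
            je = lcm[j + 1]
            if je - jb > 1 and xs[je] != xs[jb]:
                c = (je - jb) / (xs[je] - xs[jb])
                for jj in range(jb, je + 1):
                    t = (xs[jj] - xs[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dip = max(dip, dip_l, dip_u)
        new_low, new_high = gcm[ig], lcm[ih]
        if new_low == low and new_high == high:
            break
        low, high = new_low, new_high

    return dip / (2.0 * n)


# ---------------------------------------------------------------------------
# bootstrap dip test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DipResult:
    """Dip statistic with a Monte-Carlo uniform-null p-value."""

    dip: float
    p_value: float
    n_boot: int
    sample_size: int


_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def dip_null_table(n: int, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """Sorted dip statistics of ``n_boot`` uniform(0, 1) samples of size ``n``.

    The uniform distribution is the conventional least-favorable null for
    the dip test; the table depends only on (n, n_boot), so it can be shared
    across subjects and replicates.
    """
    table = np.empty(n_boot)
    for b in range(n_boot):
        table[b] = dip_statistic(rng.uniform(size=n))
    table.sort()
    return table


def dip_test(sample, n_boot: int = 1000, rng=None, null_table=None) -> DipResult:
    """Dip test against the uniform null.

    The p-value is the proportion of ``n_boot`` uniform samples of the same
    size whose dip is at least the observed dip.  ``null_table`` may carry a
    precomputed table from :func:`dip_null_table` (useful when many samples
    of the same size are tested); otherwise one is drawn from ``rng``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    x = np.asarray(sample, dtype=float)
    d = dip_statistic(x)
    if null_table is None:
        if rng is None:
            rng = np.random.default_rng()
        null_table = dip_null_table(x.size, n_boot, rng)
    else:
        null_table = np.asarray(null_table)
        n_boot = null_table.size
    p = float(np.mean(null_table >= d))
    return DipResult(dip=d, p_value=p, n_boot=n_boot, sample_size=int(x.size))


# ---------------------------------------------------------------------------
# race-model independence check
# ---------------------------------------------------------------------------

def independence_check(records: pd.DataFrame) -> dict:
    """Race-model independence check for one subject, per condition.

    The independent race predicts that failed-stop responses are drawn from
    the fast tail of the go RT distribution, hence strictly
    ``mean(failed-stop RT) < mean(go RT)`` in every condition.  Conditions
    without any failed stop (or without any responded go trial) are reported
    as not evaluable and do not fail the subject.

    Returns a dict with per-condition entries
    ``{condition: {"evaluable", "passed", "mean_go_rt", "mean_failed_stop_rt"}}``
    and an overall ``"passed"`` flag (True unless some evaluable condition
    fails).
    """
    out: dict = {"per_condition": {}, "passed": True}
    for cond, sub in records.groupby("condition", observed=True):
        go_rts = sub.loc[
            (sub["trial_type"] == "go") & sub["rt_ms"].notna(), "rt_ms"
        ]
        fs_rts = sub.loc[
            (sub["trial_type"] == "stop") & (sub["outcome"] == "failed_stop"),
            "rt_ms",
        ].dropna()
        entry = {
            "evaluable": len(fs_rts) > 0 and len(go_rts) > 0,
            "mean_go_rt": float(go_rts.mean()) if len(go_rts) else float("nan"),
            "mean_failed_stop_rt": float(fs_rts.mean()) if len(fs_rts) else float("nan"),
        }
        if entry["evaluable"]:
            entry["passed"] = bool(entry["mean_failed_stop_rt"] < entry["mean_go_rt"])
            if not entry["passed"]:
                out["passed"] = False
        else:
            entry["passed"] = None
        out["per_condition"][str(cond)] = entry
    return out


# ---------------------------------------------------------------------------
# cohort screening
# ---------------------------------------------------------------------------

@dataclass
class SubjectScreening:
    subject_id: str
    included: bool
    exclusion_reasons: list = field(default_factory=list)
    dip_ssd: dict = field(default_factory=dict)  # condition -> DipResult
    dip_rt: dict = field(default_factory=dict)
    independence: dict = field(default_factory=dict)
    p_respond: dict = field(default_factory=dict)


@dataclass
class ScreeningReport:
    subjects: dict  # subject_id -> SubjectScreening
    alpha: float
    n_boot: int

    @property
    def included_ids(self) -> list:
        return [s for s, r in self.subjects.items() if r.included]

    @property
    def excluded_ids(self) -> list:
        return [s for s, r in self.subjects.items() if not r.included]

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_boot": self.n_boot,
            "subjects": {
                sid: {
                    "included": r.included,
                    "exclusion_reasons": list(r.exclusion_reasons),
                    "p_respond": r.p_respond,
                    "dip_ssd": {
                        c: {"dip": d.dip, "p_value": d.p_value}
                        for c, d in r.dip_ssd.items()
                    },
                    "dip_rt": {
                        c: {"dip": d.dip, "p_value": d.p_value}
                        for c, d in r.dip_rt.items()
                    },
                    "independence": r.independence,
                }
                for sid, r in self.subjects.items()
            },
        }


def screen_cohort(
    trials: pd.DataFrame,
    alpha: float = 0.05,
    n_boot: int = 1000,
    rng=None,
    phase: str = "test",
    ssd_dither_ms: float = 25.0,
) -> ScreeningReport:
    """Screen every subject of a trial table.

    A subject is excluded when (i) the dip test on any condition's
    stop-trial SSDs rejects unimodality at ``alpha``, (ii) the race-model
    independence check fails in an evaluable condition, or (iii) any
    condition's p(respond) on stop trials falls outside the closed window
    [0.35, 0.65].  RT dip tests are reported for completeness but do not
    drive exclusion.  Bootstrap null tables are shared across subjects with
    equal sample sizes, so screening is order-independent.

    Staircase SSDs live on a coarse grid (multiples of the staircase step),
    and the dip statistic of heavily tied samples is dominated by the ties
    rather than by the shape of the trajectory: every clean staircase run
    would reject against the continuous uniform null.  ``ssd_dither_ms``
    therefore dequantizes the SSDs with seeded uniform jitter of +/- half a
    step (the standard continuity correction) before the dip test; set it
    to 0 to test the raw grid values.
    """
    if rng is None:
        rng = np.random.default_rng()
    data = trials[trials["phase"] == phase]
    if data.empty:
        raise ValueError(f"no records for phase {phase!r}")
    null_tables: dict[int, np.ndarray] = {}

    def get_table(n: int) -> np.ndarray:
        if n not in null_tables:
            null_tables[n] = dip_null_table(n, n_boot, rng)
        return null_tables[n]

    subjects = {}
    for sid in sorted(data["subject_id"].unique()):
        sub = data[data["subject_id"] == sid]
        rec = SubjectScreening(subject_id=str(sid), included=True)
        for cond, cs in sub.groupby("condition", observed=True):
            cond = str(cond)
            stop = cs[cs["trial_type"] == "stop"]
            if len(stop):
                p_resp = float((stop["outcome"] == "failed_stop").mean())
                rec.p_respond[cond] = p_resp
                lo, hi = P_RESPOND_WINDOW
                if not (lo <= p_resp <= hi):
                    rec.exclusion_reasons.append(f"p_respond_window:{cond}")
                ssd = stop["ssd_ms"].to_numpy(dtype=float)
                if len(ssd) >= 2:
                    if ssd_dither_ms > 0:
                        ssd = ssd + rng.uniform(
                            -ssd_dither_ms, ssd_dither_ms, size=len(ssd)
                        )
                    res = dip_test(ssd, n_boot, null_table=get_table(len(ssd)))
                    rec.dip_ssd[cond] = res
                    if res.p_value < alpha:
                        rec.exclusion_reasons.append(f"ssd_multimodal:{cond}")
            go_rt = cs.loc[
                (cs["trial_type"] == "go") & cs["rt_ms"].notna(), "rt_ms"
            ].to_numpy(dtype=float)
            if len(go_rt) >= 2:
                rec.dip_rt[cond] = dip_test(
                    go_rt, n_boot, null_table=get_table(len(go_rt))
                )
        rec.independence = independence_check(sub)
        if not rec.independence["passed"]:
            rec.exclusion_reasons.append("race_model_independence")
        rec.included = not rec.exclusion_reasons
        subjects[str(sid)] = rec
    return ScreeningReport(subjects=subjects, alpha=alpha, n_boot=n_boot)
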