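"""Per subject x condition behavioral variables of the stop-signal task.

The central quantity is the stop-signal reaction time (SSRT) estimated with
the integration method: under the independent race, the subject responds on
a stop trial iff the go process finishes within ``SSD + SSRT``, so the
p(respond) quantile of the go RT distribution sits at ``mean SSD + SSRT``.
Go omissions are replaced by the maximum observed go RT before taking the
quantile (omissions are arbitrarily slow go finishes).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SubjectConditionSummary",
    "summarize",
    "summarize_cohort",
    "ssrt_integration",
    "cohort_table",
    "long_run_stop_failure_rate",
]


@dataclass(frozen=True)
class SubjectConditionSummary:
    subject_id: str
    condition: str
    n_go: int
    n_stop: int
    mean_rt_ms: float
    sd_rt_ms: float
    p_go_omission: float
    p_respond: float  # NaN when no stop trials
    mean_ssd_ms: float
    ssrt_ms: float  # NaN when undefined
    ssrt_defined: bool


def ssrt_integration(go_rts_ms, p_respond: float, mean_ssd_ms: float) -> float:
    """Integration-method SSRT with go-omission replacement.

    ``go_rts_ms`` is the full go RT list — choice-error RTs included,
    omissions as NaN.  Omissions are replaced by the maximum observed RT,
    the list is sorted, and the rank-``ceil(p_respond * N)`` order statistic
    (clamped to [1, N], no interpolation) minus the mean SSD is returned.
    Undefined (NaN) when p_respond is 0 or 1: the quantile then sits at the
    edge of the distribution and the estimator breaks down.
    """
    rts = np.asarray(go_rts_ms, dtype=float)
    if rts.size == 0 or np.all(np.isnan(rts)):
        raise ValueError("ssrt_integration needs at least one non-omitted go RT")
    if not (0.0 < p_respond < 1.0):
        return float("nan")
    finite = rts[~np.isnan(rts)]
    filled = np.where(np.isnan(rts), finite.max(), rts)
    filled.sort()
    n = filled.size
    rank = min(max(math.ceil(p_respond * n), 1), n)
    return float(filled[rank - 1] - mean_ssd_ms)


def summarize(records: pd.DataFrame) -> SubjectConditionSummary:
    """Summary of one subject x condition cell of a trial table."""
    if records.empty:
        raise ValueError("empty record set")
    sid = str(records["subject_id"].iloc[0])
    cond = str(records["condition"].iloc[0])
    go = records[records["trial_type"] == "go"]
    stop = records[records["trial_type"] == "stop"]
    n_go, n_stop = len(go), len(stop)
    if n_go == 0:
        raise ValueError(f"no go trials for {sid}/{cond}")

    go_rts = go["rt_ms"].to_numpy(dtype=float)  # NaN marks omissions
    observed = go_rts[~np.isnan(go_rts)]
    p_om = float(np.isnan(go_rts).mean())
    mean_rt = float(observed.mean()) if observed.size else float("nan")
    sd_rt = float(observed.std(ddof=1)) if observed.size > 1 else float("nan")

    if n_stop:
        p_resp = float((stop["outcome"] == "failed_stop").mean())
        mean_ssd = float(stop["ssd_ms"].mean())
        ssrt = (
            ssrt_integration(go_rts, p_resp, mean_ssd) if observed.size else float("nan")
        )
    else:
        p_resp = mean_ssd = ssrt = float("nan")
    return SubjectConditionSummary(
        subject_id=sid,
        condition=cond,
        n_go=n_go,
        n_stop=n_stop,
        mean_rt_ms=mean_rt,
        sd_rt_ms=sd_rt,
        p_go_omission=p_om,
        p_respond=p_resp,
        mean_ssd_ms=mean_ssd,
        ssrt_ms=ssrt,
        ssrt_defined=bool(not math.isnan(ssrt)),
    )


def summarize_cohort(trials: pd.DataFrame, phase: str = "test") -> pd.DataFrame:
    """One summary row per subject x condition (test phase by default)."""
    data = trials[trials["phase"] == phase]
    rows = [
        summarize(sub).__dict__
        for (_, _), sub in data.groupby(["subject_id", "condition"], observed=True)
    ]
    return pd.DataFrame(rows).sort_values(["subject_id", "condition"]).reset_index(drop=True)


def cohort_table(summaries: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Subjects x conditions matrix of one summary variable.

    Raises a ``ValueError`` naming the missing subject/condition cell if the
    design is incomplete.
    """
    mat = summaries.pivot(index="subject_id", columns="condition", values=variable)
    if mat.isna().any().any():
        missing = [
            f"{mat.index[i]}/{mat.columns[j]}"
            for i, j in zip(*np.where(mat.isna().to_numpy()))
        ]
        raise ValueError(f"incomplete design, missing cells: {', '.join(missing)}")
    return mat


def long_run_stop_failure_rate(
    trials: pd.DataFrame, phase: str = "test", burn_in_fraction: float = 0.5
) -> pd.DataFrame:
    """Stationary failed-stop rate of the tracking staircase, per condition.

    The staircase starts at its lower bound and first climbs to the SSD
    where the go and stop processes race evenly; during that ascent almost
    every stop trial is a correct stop, which biases the raw failed-stop
    proportion below the 0.5 tracking point (each net up-step costs exactly
    half a failed stop).  The long-run rate discards the first
    ``burn_in_fraction`` of each subject x condition staircase's stop
    trials — the standard burn-in estimator for a stationary rate of a
    Markov chain; once both endpoints of the retained stretch are
    stationary, up- and down-steps balance and the expected rate is the
    0.5 tracking point.  (The raw proportion over all stop trials is what
    ``p_respond`` in the subject summaries reports.)

    Returns a tidy frame with subject_id, condition, n_used and rate.
    """
    if not (0.0 <= burn_in_fraction < 1.0):
        raise ValueError("burn_in_fraction must be in [0, 1)")
    data = trials[(trials["phase"] == phase) & (trials["trial_type"] == "stop")]
    rows = []
    for (sid, cond), sub in data.groupby(["subject_id", "condition"], observed=True):
        failed = (sub["outcome"] == "failed_stop").to_numpy()
        start = int(math.floor(burn_in_fraction * failed.size))
        tail = failed[start:]
        rows.append(
            {
                "subject_id": sid,
                "condition": cond,
                "n_used": int(tail.size),
                "rate": float(tail.mean()) if tail.size else float("nan"),
            }
        )
    return pd.DataFrame(rows)
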