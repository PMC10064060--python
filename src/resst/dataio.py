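"""Readers, writers, configuration and the end-to-end pipeline.

Trial tables travel as tidy CSV (one row per trial, missing values as
empty fields, lossless round-trip); session and agent configurations as
YAML/JSON mirroring the dataclass field names.  A single root seed spawns
per-stage child seeds deterministically, so one integer reproduces a whole
simulated study.
"""
from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ddm as ddm_mod
from .agents import (
    DEFAULT_HETEROGENEITY,
    DEFAULT_TEMPLATE,
    CohortSpec,
    DDMAgent,
    DDMAgentParams,
    RaceAgent,
    RaceAgentParams,
    make_cohort,
    simulate_cohort,
)
from .metrics import cohort_table, long_run_stop_failure_rate, summarize_cohort
from .prevalence import prevalence_from_cohort
from .qc import screen_cohort
from .stats import friedman, pearson, rm_anova, tukey_kramer
from .task_engine import TRIAL_COLUMNS, SessionConfig

__all__ = [
    "read_trials",
    "write_trials",
    "load_session_config",
    "load_agent_params",
    "stage_seeds",
    "RunManifest",
    "report",
]

_MANDATORY = [c for c in TRIAL_COLUMNS if c != "block"]


def read_trials(path) -> pd.DataFrame:
    """Read a trial-table CSV; missing mandatory columns are schema errors."""
    df = pd.read_csv(path)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"trial table schema error, missing column(s): {', '.join(missing)}")
    if "block" not in df.columns:
        df["block"] = 0
    df["responded"] = df["responded"].astype(bool)
    for col in ("ssd_ms", "rt_ms"):
        df[col] = pd.to_numeric(df[col])
    df["response_direction"] = df["response_direction"].fillna("none")
    return df


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as CSV with empty fields for missing values."""
    trials.to_csv(path, index=False)


def load_session_config(path) -> SessionConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "reward_matrix" in raw:
        raw["reward_matrix"] = {
            (cond, tt): pts
            for cond, by_type in raw["reward_matrix"].items()
            for tt, pts in by_type.items()
        }
    for key in ("conditions", "condition_fractions", "cue_go_delay_ms"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return SessionConfig(**raw)


def load_agent_params(path):
    """Agent parameter file with a ``kind: race|ddm`` key."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    kind = raw.pop("kind", "race")
    if kind == "race":
        return RaceAgentParams(**raw)
    if kind == "ddm":
        ssrt = raw.pop("ssrt_ms", 230.0)
        params = DDMAgentParams(**raw)
        return params if ssrt is None else (params, ssrt)
    raise ValueError(f"unknown agent kind {kind!r}")


def stage_seeds(root_seed: int, stages=("simulate", "qc", "metrics", "stats", "prevalence", "ddm")):
    """Deterministic per-stage child seeds spawned from one root seed."""
    ss = np.random.SeedSequence(root_seed)
    children = ss.spawn(len(stages))
    return {name: int(c.generate_state(1)[0] % (2**31)) for name, c in zip(stages, children)}


@dataclass
class RunManifest:
    seed: int
    stage_seeds: dict
    config: dict
    runtimes_s: dict = field(default_factory=dict)

    def to_dict(self):
        return {
            "seed": self.seed,
            "stage_seeds": self.stage_seeds,
            "config": self.config,
            "runtimes_s": self.runtimes_s,
        }


def report(
    seed: int = 0,
    n_subjects: int = 14,
    config: SessionConfig | None = None,
    heterogeneity: dict | None = None,
    run_ddm: bool = True,
    ddm_restarts: int = 3,
    out_dir=None,
    prevalence_pairs=(("Gplus", "Neutral"), ("Gplus", "Splus"), ("Splus", "Neutral")),
) -> dict:
    """End-to-end demo study: simulate -> qc -> metrics -> stats -> prevalence -> ddm.

    Returns a JSON-serializable summary; with ``out_dir`` the trial table,
    screening report and summary are written there.  Reruns with the same
    seed are bit-identical (modulo runtimes).
    """
    t_all = time.time()
    seeds = stage_seeds(seed)
    manifest = RunManifest(seed=seed, stage_seeds=seeds, config={"n_subjects": n_subjects})
    out: dict = {"seeds": seeds}

    def _timed(name, fn):
        t0 = time.time()
        res = fn()
        manifest.runtimes_s[name] = round(time.time() - t0, 3)
        return res

    cfg = config or SessionConfig()
    spec = CohortSpec(
        n_subjects=n_subjects,
        template=DEFAULT_TEMPLATE,
        heterogeneity=heterogeneity if heterogeneity is not None else DEFAULT_HETEROGENEITY,
        seed=seeds["simulate"],
    )
    trials = _timed(
        "simulate", lambda: simulate_cohort(make_cohort(spec), cfg, seed=seeds["simulate"])
    )

    screening = _timed(
        "qc",
        lambda: screen_cohort(trials, rng=np.random.default_rng(seeds["qc"])),
    )
    kept = trials[trials["subject_id"].isin(screening.included_ids)]
    if kept.empty:
        raise ValueError("qc stage excluded every subject; nothing to analyze")
    out["qc"] = {
        "n_subjects": n_subjects,
        "n_included": len(screening.included_ids),
        "excluded": {
            sid: screening.subjects[sid].exclusion_reasons
            for sid in screening.excluded_ids
        },
    }

    summaries = _timed("metrics", lambda: summarize_cohort(kept))
    out["condition_means"] = {
        var: cohort_table(summaries, var).mean(axis=0).round(2).to_dict()
        for var in ("mean_rt_ms", "ssrt_ms", "mean_ssd_ms", "p_respond", "p_go_omission")
    }
    lr = long_run_stop_failure_rate(kept)
    out["long_run_stop_failure_rate"] = round(float(lr["rate"].mean()), 4)

    def _stats():
        block: dict = {}
        for var in ("mean_rt_ms", "ssrt_ms", "mean_ssd_ms", "p_respond"):
            mat = cohort_table(summaries, var)
            an = rm_anova(mat)
            block[var] = {
                "F": round(an.F, 3),
                "df": [an.df_effect, an.df_error],
                "p": an.p_value,
                "eta2p": round(an.eta2p, 4),
                "tukey_kramer": tukey_kramer(mat).comparisons,
            }
        rt = cohort_table(summaries, "mean_rt_ms").to_numpy().ravel()
        ssrt = cohort_table(summaries, "ssrt_ms").to_numpy().ravel()
        ssd = cohort_table(summaries, "mean_ssd_ms").to_numpy().ravel()
        block["corr_rt_ssrt"] = pearson(rt, ssrt).__dict__
        block["corr_rt_ssd"] = pearson(rt, ssd).__dict__
        return block

    out["stats"] = _timed("stats", _stats)

    def _prev():
        block = {}
        for pair in prevalence_pairs:
            post, _ = prevalence_from_cohort(kept, pair)
            block["_vs_".join(pair)] = post.to_dict()
        return block

    out["prevalence"] = _timed("prevalence", _prev)

    if run_ddm:
        def _ddm():
            rng = np.random.default_rng(seeds["ddm"])
            fits = {}
            for sid in sorted(kept["subject_id"].unique()):
                sub = kept[kept["subject_id"] == sid]
                fits[sid] = {
                    var: ddm_mod.fit_subject(sub, var, n_restarts=ddm_restarts, rng=rng)
                    for var in ddm_mod.VARIANTS
                }
            comp = ddm_mod.compare_models(fits)
            return {
                "selection_counts": comp["selection_counts"],
                "bic_sums": {k: round(v, 1) for k, v in comp["bic_sums"].items()},
                "best_by_subject": comp["best_by_subject"],
            }

        out["ddm"] = _timed("ddm", _ddm)

    manifest.runtimes_s["total"] = round(time.time() - t_all, 3)
    out["manifest"] = manifest.to_dict()

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_trials(trials, out_dir / "trials.csv")
        with open(out_dir / "screening.json", "w") as fh:
            json.dump(screening.to_dict(), fh, indent=2)
        summaries.to_csv(out_dir / "summaries.csv", index=False)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(out, fh, indent=2, default=float)
    return out
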