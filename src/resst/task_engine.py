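"""Reward-cued stop-signal task engine.

Generates trial schedules and runs sessions against a behavioral agent.
Each trial starts with a cue announcing the reward schedule (Go+ / Neutral /
Stop+: 30/5, 17/17 or 5/30 points for a correct go/stop trial), followed by
a go signal; on 30% of trials a stop signal appears after a staircase-
tracked stop-signal delay (SSD).  One independent 50-ms up/down staircase
per condition keeps the probability of responding on stop trials near 0.5.

All times are integer-valued milliseconds at this layer; agents may compute
in seconds internally but must return milliseconds.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "DEFAULT_REWARD_MATRIX",
    "SessionConfig",
    "TrialSpec",
    "StaircaseState",
    "TrialRecord",
    "build_schedule",
    "staircase_update",
    "reward_for",
    "run_session",
    "records_to_frame",
    "TRIAL_COLUMNS",
]

CONDITIONS = ("Gplus", "Neutral", "Splus")

#: points per (condition, trial_type) for *correct* trials
DEFAULT_REWARD_MATRIX = {
    ("Gplus", "go"): 30,
    ("Gplus", "stop"): 5,
    ("Neutral", "go"): 17,
    ("Neutral", "stop"): 17,
    ("Splus", "go"): 5,
    ("Splus", "stop"): 30,
}

TRIAL_COLUMNS = [
    "subject_id",
    "phase",
    "block",
    "trial_index",
    "condition",
    "trial_type",
    "go_direction",
    "ssd_ms",
    "responded",
    "response_direction",
    "rt_ms",
    "outcome",
    "reward_points",
]


@dataclass(frozen=True)
class SessionConfig:
    """Configuration of one session (a learning block or the test block)."""

    phase: str = "test"
    n_trials: int = 600
    stop_fraction: float = 0.30
    conditions: tuple = CONDITIONS
    condition_fractions: tuple | None = None  # default: equal shares
    ssd_initial_ms: int = 50
    ssd_step_ms: int = 50
    ssd_min_ms: int = 50
    ssd_max_ms: int = 1000
    rt_limit_ms: int = 1500
    iti_ms: int = 500
    cue_go_delay_ms: tuple = (900, 1200)
    reward_matrix: dict = field(default_factory=lambda: dict(DEFAULT_REWARD_MATRIX))
    seed: int | None = None

    def __post_init__(self):
        if self.phase not in ("learning", "test"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if not (0.0 < self.stop_fraction < 1.0):
            raise ValueError("stop_fraction must be in (0, 1)")
        if self.condition_fractions is None:
            object.__setattr__(
                self,
                "condition_fractions",
                tuple(1.0 / len(self.conditions) for _ in self.conditions),
            )
        if len(self.condition_fractions) != len(self.conditions):
            raise ValueError("condition_fractions must match conditions")
        if abs(sum(self.condition_fractions) - 1.0) > 1e-12:
            raise ValueError("condition_fractions must sum to 1")
        if not (self.ssd_min_ms <= self.ssd_initial_ms <= self.ssd_max_ms):
            raise ValueError("require ssd_min_ms <= ssd_initial_ms <= ssd_max_ms")
        if self.ssd_step_ms <= 0:
            raise ValueError("ssd_step_ms must be positive")
        for cond in self.conditions:
            for tt in ("go", "stop"):
                if (cond, tt) not in self.reward_matrix:
                    raise ValueError(f"reward_matrix missing ({cond}, {tt})")


@dataclass(frozen=True)
class TrialSpec:
    index: int
    condition: str
    trial_type: str  # "go" | "stop"
    go_direction: str  # "left" | "right"


@dataclass(frozen=True)
class StaircaseState:
    """Current SSD of one condition's tracking procedure."""

    condition: str
    ssd_ms: int
    step_ms: int = 50
    min_ms: int = 50
    max_ms: int = 1000

    def __post_init__(self):
        if not (self.min_ms <= self.ssd_ms <= self.max_ms):
            raise ValueError("ssd_ms outside [min_ms, max_ms]")


@dataclass(frozen=True)
class TrialRecord:
    subject_id: str
    phase: str
    block: int
    trial_index: int
    condition: str
    trial_type: str
    go_direction: str
    ssd_ms: float  # NaN on go trials
    responded: bool
    response_direction: str  # "left" | "right" | "none"
    rt_ms: float  # NaN on omissions / correct stops
    outcome: str
    reward_points: int


def _int_count(value: float, what: str) -> int:
    if abs(value - round(value)) > 1e-9:
        raise ValueError(
            f"configuration error: {what} = {value} is not an integer count"
        )
    return int(round(value))


def build_schedule(config: SessionConfig, rng: np.random.Generator) -> list:
    """Exact-count randomized trial schedule.

    Every (condition, trial type) cell receives exactly
    ``n_trials * condition_fraction * stop_fraction`` (or the go complement)
    trials; a non-integral count is a configuration error.  The order is a
    seeded permutation, so schedule counts are deterministic while the
    sequence is random.
    """
    specs = []
    for cond, frac in zip(config.conditions, config.condition_fractions):
        n_cond = _int_count(config.n_trials * frac, f"trials for {cond}")
        n_stop = _int_count(n_cond * config.stop_fraction, f"stop trials for {cond}")
        n_go = n_cond - n_stop
        specs.extend(("stop", cond) for _ in range(n_stop))
        specs.extend(("go", cond) for _ in range(n_go))
    order = rng.permutation(len(specs))
    out = []
    for i, j in enumerate(order):
        tt, cond = specs[j]
        direction = "left" if rng.random() < 0.5 else "right"
        out.append(TrialSpec(index=i, condition=cond, trial_type=tt, go_direction=direction))
    return out


def staircase_update(state: StaircaseState, outcome: str) -> StaircaseState:
    """One step of the tracking rule.

    A correct stop makes inhibition harder next time (SSD up one step); a
    failed stop makes it easier (SSD down one step); the SSD is clamped to
    the configured bounds.
    """
    if outcome == "correct_stop":
        new = state.ssd_ms + state.step_ms
    elif outcome == "failed_stop":
        new = state.ssd_ms - state.step_ms
    else:
        raise ValueError(f"staircase_update needs a stop-trial outcome, got {outcome!r}")
    new = min(max(new, state.min_ms), state.max_ms)
    return replace(state, ssd_ms=new)


def reward_for(condition: str, trial_type: str, outcome: str, reward_matrix=None) -> int:
    """Points for a trial: the matrix value for correct trials, 0 otherwise."""
    if reward_matrix is None:
        reward_matrix = DEFAULT_REWARD_MATRIX
    if (condition, trial_type) not in reward_matrix:
        raise KeyError(f"unknown condition/trial type ({condition!r}, {trial_type!r})")
    if outcome in ("correct_go", "correct_stop"):
        return int(reward_matrix[(condition, trial_type)])
    if outcome in ("failed_go_wrongkey", "go_omission", "failed_stop"):
        return 0
    raise ValueError(f"unknown outcome {outcome!r}")


def run_session(
    schedule,
    agent,
    config: SessionConfig,
    rng: np.random.Generator,
    subject_id: str = "s01",
    block: int = 0,
    initial_staircases: dict | None = None,
) -> list:
    """Run a full session of the task against an agent.

    The agent must expose ``respond(condition, trial_type, ssd_ms,
    go_direction, rng) -> (responded, rt_ms, direction)``.  One independent
    staircase per condition is kept; it starts at ``ssd_initial_ms`` unless
    ``initial_staircases`` carries states from a previous block (carry-over
    between phases is configurable because the original procedure does not
    state whether test-phase staircases were re-initialized).

    Go responses later than ``rt_limit_ms`` are recorded as go omissions;
    a response on a stop trial before the limit is a failed stop regardless
    of the key pressed.
    """
    staircases = {
        cond: StaircaseState(
            condition=cond,
            ssd_ms=config.ssd_initial_ms,
            step_ms=config.ssd_step_ms,
            min_ms=config.ssd_min_ms,
            max_ms=config.ssd_max_ms,
        )
        for cond in config.conditions
    }
    if initial_staircases:
        staircases.update(initial_staircases)

    records = []
    for spec in schedule:
        is_stop = spec.trial_type == "stop"
        ssd = staircases[spec.condition].ssd_ms if is_stop else None
        responded, rt, direction = agent.respond(
            spec.condition, spec.trial_type, ssd, spec.go_direction, rng
        )
        if responded and (rt is None or rt < 0 or not math.isfinite(rt)):
            raise ValueError(f"agent returned invalid RT {rt!r}")
        if responded and rt > config.rt_limit_ms:
            responded, rt, direction = False, None, None

        if is_stop:
            if responded:
                outcome = "failed_stop"
            else:
                outcome = "correct_stop"
            staircases[spec.condition] = staircase_update(
                staircases[spec.condition], outcome
            )
        else:
            if not responded:
                outcome = "go_omission"
            elif direction == spec.go_direction:
                outcome = "correct_go"
            else:
                outcome = "failed_go_wrongkey"

        keep_rt = responded and outcome not in ("go_omission",)
        records.append(
            TrialRecord(
                subject_id=subject_id,
                phase=config.phase,
                block=block,
                trial_index=spec.index,
                condition=spec.condition,
                trial_type=spec.trial_type,
                go_direction=spec.go_direction,
                ssd_ms=float(ssd) if is_stop else float("nan"),
                responded=bool(responded),
                response_direction=direction if responded else "none",
                rt_ms=float(rt) if keep_rt else float("nan"),
                outcome=outcome,
                reward_points=reward_for(
                    spec.condition, spec.trial_type, outcome, config.reward_matrix
                ),
            )
        )
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Tidy trial table (one row per trial) from a list of records."""
    return pd.DataFrame([r.__dict__ for r in records], columns=TRIAL_COLUMNS)
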