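"""Synthetic behavioral agents.

Two generative models of task behavior:

* :class:`RaceAgent` — the independent horse race.  Go finish times are
  ex-Gaussian (the standard parametric surrogate for RT distributions);
  on stop trials the subject responds iff the go process finishes before
  ``SSD + SSRT``.  Context independence holds by construction: the go
  finish-time draw does not depend on the SSD.

* :class:`DDMAgent` — a drift-diffusion go process with cue-dependent
  starting point and/or drift (Ratcliff convention, within-trial noise
  s = 0.1, seconds internally, milliseconds at the module boundary).

:func:`make_cohort` draws per-subject parameter sets around a template;
the shipped :data:`DEFAULT_TEMPLATE` is calibrated so that a simulated
cohort reproduces the study-level behavioral pattern (go RT means near
619/652/686 ms across the three cue conditions and SSRTs near 230-253 ms).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .task_engine import (
    CONDITIONS,
    SessionConfig,
    build_schedule,
    records_to_frame,
    run_session,
)

__all__ = [
    "RaceAgentParams",
    "DDMAgentParams",
    "CohortSpec",
    "RaceAgent",
    "DDMAgent",
    "race_trial",
    "ddm_trial",
    "ddm_sample",
    "ddm_sample_coupled",
    "make_cohort",
    "simulate_cohort",
    "DEFAULT_TEMPLATE",
    "DEFAULT_HETEROGENEITY",
    "DEFAULT_DDM_TEMPLATE",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RaceAgentParams:
    """Independent-race agent: per-condition ex-Gaussian go process + SSRT.

    ``mu``, ``sigma``, ``tau`` map condition -> ex-Gaussian parameters (ms);
    ``ssrt`` maps condition -> true stop latency (ms).  ``p_go_omission`` is
    an attentional-lapse probability on go trials, ``p_choice_error`` flips
    the reported key, ``p_trigger_failure`` is the probability the stop
    process never starts (default 0: the integration-method estimator
    ignores trigger failures, the knob exists to stress-test it), and
    ``ssrt_noise_sd`` adds trial-to-trial Gaussian noise to the SSRT.
    """

    mu: dict
    sigma: dict
    tau: dict
    ssrt: dict
    p_go_omission: float = 0.0
    p_choice_error: float = 0.0
    p_trigger_failure: float = 0.0
    ssrt_noise_sd: float = 0.0

    def __post_init__(self):
        for cond in self.mu:
            if self.sigma[cond] <= 0:
                raise ValueError(f"sigma must be > 0 ({cond})")
            if self.tau[cond] < 0:
                raise ValueError(f"tau must be >= 0 ({cond})")
            if self.ssrt[cond] <= 0:
                raise ValueError(f"ssrt must be > 0 ({cond})")
        for name in ("p_go_omission", "p_choice_error", "p_trigger_failure"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.ssrt_noise_sd < 0:
            raise ValueError("ssrt_noise_sd must be >= 0")


@dataclass(frozen=True)
class DDMAgentParams:
    """Diffusion go process with per-condition starting point and drift.

    ``a`` boundary separation, ``z`` condition -> starting point (0 < z < a),
    ``v`` condition -> drift (evidence/s), ``ter`` non-decision time (s),
    ``sz`` uniform starting-point range, ``st`` uniform non-decision range
    (s), ``eta`` across-trial drift SD, ``s`` within-trial noise (fixed 0.1
    by convention).
    """

    a: float
    z: dict
    v: dict
    ter: float
    sz: float = 0.0
    st: float = 0.0
    eta: float = 0.0
    s: float = 0.1

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("a must be > 0")
        for cond, zc in self.z.items():
            if not (0.0 < zc - self.sz / 2 and zc + self.sz / 2 < self.a):
                raise ValueError(f"z +/- sz/2 must stay inside (0, a) ({cond})")
        if self.ter - self.st / 2 < 0:
            raise ValueError("ter - st/2 must be >= 0")
        if self.eta < 0 or self.sz < 0 or self.st < 0:
            raise ValueError("eta, sz, st must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort: template + between-subject spread.

    ``heterogeneity`` maps parameter names to between-subject SDs:
    ``mu_shared`` shifts all conditions' mu together (a subject's overall
    speed), while ``mu``, ``sigma``, ``tau``, ``ssrt`` jitter each condition
    independently.  Sampled parameter sets must satisfy the agent
    invariants; violating draws are resampled (up to 100 times).
    """

    n_subjects: int
    template: RaceAgentParams
    heterogeneity: dict = field(default_factory=dict)
    seed: int | None = None


#: Calibrated race-agent template.  Ex-Gaussian means mu + tau equal the
#: study-level go RT means (619/652/686 ms); the within-subject trial SD
#: sqrt(sigma^2 + tau^2) ~ 174 ms is typical for stop-signal go RTs.
DEFAULT_TEMPLATE = RaceAgentParams(
    mu={"Gplus": 484.0, "Neutral": 517.0, "Splus": 551.0},
    sigma={c: 110.0 for c in CONDITIONS},
    tau={c: 135.0 for c in CONDITIONS},
    ssrt={"Gplus": 230.0, "Neutral": 253.0, "Splus": 230.0},
    p_go_omission=0.02,
    p_choice_error=0.01,
)

#: Between-subject spread: a large shared speed factor plus small
#: condition-specific jitter keeps the within-subject condition ordering
#: (the pattern the study reports) while giving realistic subject scatter.
DEFAULT_HETEROGENEITY = {
    "mu_shared": 55.0,
    "mu": 12.0,
    "sigma": 15.0,
    "tau": 20.0,
    "ssrt": 20.0,
}

#: DDM template with a starting-point (z) cue bias: z closer to the correct
#: boundary under Go+, centered under Neutral, lower under Stop+.
DEFAULT_DDM_TEMPLATE = DDMAgentParams(
    a=0.16,
    z={"Gplus": 0.096, "Neutral": 0.080, "Splus": 0.064},
    v={c: 0.25 for c in CONDITIONS},
    ter=0.30,
    eta=0.08,
)


# ---------------------------------------------------------------------------
# race agent
# ---------------------------------------------------------------------------

def _exgauss(mu, sigma, tau, rng):
    t = mu + sigma * rng.standard_normal()
    if tau > 0:
        t += rng.exponential(tau)
    return t


def race_trial(
    params: RaceAgentParams,
    condition: str,
    trial_type: str,
    ssd_ms,
    rng: np.random.Generator,
):
    """One trial of the independent race.

    Returns ``(responded, rt_ms, correct_key)``: whether the go process won,
    its finish time, and whether the reported key matches the go stimulus.
    On stop trials the subject responds iff ``T_go < SSD + SSRT`` (always,
    under a trigger failure); the ``T_go`` draw never depends on the SSD.
    """
    if condition not in params.mu:
        raise KeyError(f"unknown condition {condition!r}")
    if (ssd_ms is None) == (trial_type == "stop"):
        raise ValueError("ssd_ms must be given iff trial_type == 'stop'")
    t_go = _exgauss(params.mu[condition], params.sigma[condition], params.tau[condition], rng)
    t_go = max(t_go, 1e-3)  # finish times are positive
    correct_key = not (params.p_choice_error > 0 and rng.random() < params.p_choice_error)

    if trial_type == "go":
        if params.p_go_omission > 0 and rng.random() < params.p_go_omission:
            return False, None, True
        return True, t_go, correct_key

    if params.p_trigger_failure > 0 and rng.random() < params.p_trigger_failure:
        return True, t_go, correct_key
    ssrt = params.ssrt[condition]
    if params.ssrt_noise_sd > 0:
        ssrt = max(ssrt + params.ssrt_noise_sd * rng.standard_normal(), 1e-3)
    if t_go < ssd_ms + ssrt:
        return True, t_go, correct_key
    return False, None, True


class RaceAgent:
    """Engine-facing wrapper around :func:`race_trial`."""

    def __init__(self, params: RaceAgentParams):
        self.params = params

    def respond(self, condition, trial_type, ssd_ms, go_direction, rng):
        responded, rt, correct_key = race_trial(
            self.params, condition, trial_type, ssd_ms, rng
        )
        if not responded:
            return False, None, None
        other = "right" if go_direction == "left" else "left"
        return True, rt, go_direction if correct_key else other


# ---------------------------------------------------------------------------
# drift-diffusion agent
# ---------------------------------------------------------------------------

#: Base Euler resolution (s).  Noise is always generated at this resolution
#: so that simulating at a coarser multiple refines the *same* Brownian
#: path — the standard strong-convergence construction, which makes the
#: discretization-control comparison (dt vs dt/2) nearly noise-free.
DT_BASE = 5e-5

#: Siegmund continuity correction: a discrete walk only observes the path on
#: the grid and so crosses a continuous boundary late; shrinking the
#: boundaries by 0.5826 * s * sqrt(dt) removes the leading O(sqrt(dt)) bias.
_SIEGMUND = 0.5826


def _ddm_draw_trial_params(params, condition, n, rng):
    v = np.full(n, params.v[condition])
    if params.eta > 0:
        v = v + params.eta * rng.standard_normal(n)
    z = np.full(n, params.z[condition])
    if params.sz > 0:
        z = z + params.sz * (rng.random(n) - 0.5)
    ter = np.full(n, params.ter)
    if params.st > 0:
        ter = ter + params.st * (rng.random(n) - 0.5)
    return v, z, ter


def ddm_sample(
    params: DDMAgentParams,
    condition: str,
    n: int,
    rng: np.random.Generator,
    dt: float = 1e-4,
    t_max: float = 6.0,
):
    """Vectorized Euler simulation of ``n`` diffusion trials.

    Returns ``(choice, rt_ms)`` arrays; ``choice`` is +1 for the upper
    (correct) boundary, -1 for the lower, 0 for trials not absorbed by
    ``t_max`` (whose RT is NaN).  ``dt`` must be a multiple of the base
    resolution :data:`DT_BASE`; increments are generated at base resolution
    and aggregated, so halving ``dt`` refines the same Brownian paths.
    """
    m = dt / DT_BASE
    if abs(m - round(m)) > 1e-9 or m < 1:
        raise ValueError(f"dt must be a positive multiple of {DT_BASE}")
    m = int(round(m))
    v, z, ter = _ddm_draw_trial_params(params, condition, n, rng)
    a, s = params.a, params.s
    shrink = _SIEGMUND * s * np.sqrt(dt)
    upper, lower = a - shrink, shrink

    x = z.copy()
    choice = np.zeros(n, dtype=np.int8)
    t_dec = np.full(n, np.nan)
    active = np.arange(n)
    sqdt = s * np.sqrt(DT_BASE)
    n_steps = int(np.ceil(t_max / dt))
    for step in range(n_steps):
        if active.size == 0:
            break
        dw = rng.standard_normal((active.size, m)).sum(axis=1) * sqdt
        x[active] = x[active] + v[active] * dt + dw
        hit_up = x[active] >= upper
        hit_lo = x[active] <= lower
        hit = hit_up | hit_lo
        if hit.any():
            idx = active[hit]
            choice[idx] = np.where(hit_up[hit], 1, -1)
            t_dec[idx] = (step + 1) * dt
            active = active[~hit]
    rt_ms = (t_dec + ter) * 1000.0
    return choice, rt_ms


def ddm_sample_coupled(
    params: DDMAgentParams,
    condition: str,
    n: int,
    rng: np.random.Generator,
    dt: float = 1e-4,
    t_max: float = 6.0,
):
    """Simulate the same Brownian paths at ``dt`` and ``dt/2`` in one pass.

    Discretization-control diagnostic: both resolutions consume the same
    base-resolution increments trial by trial, so the difference between
    the two returned RT samples is pure discretization error, not Monte
    Carlo noise.  Returns ``(choice_c, rt_c, choice_f, rt_f)`` for the
    coarse (``dt``) and fine (``dt/2``) runs.
    """
    m = dt / DT_BASE
    if abs(m - round(m)) > 1e-9 or m < 2 or int(round(m)) % 2:
        raise ValueError("dt must be an even multiple of the base resolution")
    m = int(round(m))
    v, z, ter = _ddm_draw_trial_params(params, condition, n, rng)
    a, s = params.a, params.s
    up_c, lo_c = a - _SIEGMUND * s * np.sqrt(dt), _SIEGMUND * s * np.sqrt(dt)
    up_f, lo_f = a - _SIEGMUND * s * np.sqrt(dt / 2), _SIEGMUND * s * np.sqrt(dt / 2)

    xc = z.copy()
    xf = z.copy()
    choice_c = np.zeros(n, dtype=np.int8)
    choice_f = np.zeros(n, dtype=np.int8)
    t_c = np.full(n, np.nan)
    t_f = np.full(n, np.nan)
    active = np.arange(n)  # active in at least one of the two runs
    sqdt = s * np.sqrt(DT_BASE)
    n_steps = int(np.ceil(t_max / dt))
    half = m // 2
    for step in range(n_steps):
        if active.size == 0:
            break
        base = rng.standard_normal((active.size, m)) * sqdt
        dw_half = np.stack(
            [base[:, :half].sum(axis=1), base[:, half:].sum(axis=1)], axis=1
        )
        # fine run: two half-steps
        for h in range(2):
            live = choice_f[active] == 0
            xf[active] = np.where(
                live, xf[active] + v[active] * (dt / 2) + dw_half[:, h], xf[active]
            )
            hit_up = live & (xf[active] >= up_f)
            hit_lo = live & (xf[active] <= lo_f)
            idx = active[hit_up | hit_lo]
            choice_f[idx] = np.where(hit_up[hit_up | hit_lo], 1, -1)
            t_f[idx] = step * dt + (h + 1) * (dt / 2)
        # coarse run: one full step with the summed increment
        live = choice_c[active] == 0
        xc[active] = np.where(
            live, xc[active] + v[active] * dt + dw_half.sum(axis=1), xc[active]
        )
        hit_up = live & (xc[active] >= up_c)
        hit_lo = live & (xc[active] <= lo_c)
        idx = active[hit_up | hit_lo]
        choice_c[idx] = np.where(hit_up[hit_up | hit_lo], 1, -1)
        t_c[idx] = (step + 1) * dt
        active = active[(choice_c[active] == 0) | (choice_f[active] == 0)]
    return choice_c, (t_c + ter) * 1000.0, choice_f, (t_f + ter) * 1000.0


def ddm_trial(params: DDMAgentParams, condition: str, rng: np.random.Generator):
    """One diffusion trial: ``(choice, rt_ms)`` with choice 'upper'/'lower'."""
    choice, rt = ddm_sample(params, condition, 1, rng)
    while choice[0] == 0:  # not absorbed within t_max; essentially never
        choice, rt = ddm_sample(params, condition, 1, rng)
    return ("upper" if choice[0] == 1 else "lower"), float(rt[0])


class DDMAgent:
    """Engine-facing diffusion agent.

    The go process is the diffusion; reaching the upper boundary presses the
    cued key, the lower boundary the other key.  Stop trials use the race
    rule with a fixed ``ssrt_ms`` against the diffusion finish time (the
    diffusion models only the go decision).  Samples are drawn in batches
    for speed.
    """

    def __init__(self, params: DDMAgentParams, ssrt_ms: float = 230.0, batch: int = 256):
        self.params = params
        self.ssrt_ms = ssrt_ms
        self._batch = batch
        self._pool = {}

    def _draw(self, condition, rng):
        pool = self._pool.get(condition)
        if not pool:
            choice, rt = ddm_sample(self.params, condition, self._batch, rng)
            ok = choice != 0
            pool = list(zip(choice[ok].tolist(), rt[ok].tolist()))
            self._pool[condition] = pool
        return pool.pop()

    def respond(self, condition, trial_type, ssd_ms, go_direction, rng):
        choice, rt = self._draw(condition, rng)
        if trial_type == "stop" and rt >= ssd_ms + self.ssrt_ms:
            return False, None, None
        other = "right" if go_direction == "left" else "left"
        return True, rt, go_direction if choice == 1 else other


# ---------------------------------------------------------------------------
# cohort construction
# ---------------------------------------------------------------------------

def make_cohort(spec: CohortSpec) -> list:
    """Per-subject race-agent parameter sets drawn around the template."""
    rng = np.random.default_rng(spec.seed)
    het = spec.heterogeneity
    out = []
    for _ in range(spec.n_subjects):
        for attempt in range(100):
            t = spec.template
            shared = het.get("mu_shared", 0.0) * rng.standard_normal()
            mu = {
                c: t.mu[c] + shared + het.get("mu", 0.0) * rng.standard_normal()
                for c in t.mu
            }
            sigma = {
                c: t.sigma[c] + het.get("sigma", 0.0) * rng.standard_normal()
                for c in t.sigma
            }
            tau = {
                c: t.tau[c] + het.get("tau", 0.0) * rng.standard_normal()
                for c in t.tau
            }
            ssrt = {
                c: t.ssrt[c] + het.get("ssrt", 0.0) * rng.standard_normal()
                for c in t.ssrt
            }
            try:
                out.append(replace(t, mu=mu, sigma=sigma, tau=tau, ssrt=ssrt))
                break
            except ValueError:
                continue
        else:
            raise ValueError(
                "heterogeneity incompatible with parameter invariants "
                "(100 resampling attempts failed)"
            )
    return out


def simulate_cohort(
    params_list,
    config: SessionConfig | None = None,
    seed: int | None = None,
    agent_factory=RaceAgent,
) -> pd.DataFrame:
    """Run one session per subject and return the tidy trial table."""
    if config is None:
        config = SessionConfig()
    root = np.random.SeedSequence(seed)
    frames = []
    for i, (params, child) in enumerate(
        zip(params_list, root.spawn(len(params_list)))
    ):
        rng = np.random.default_rng(child)
        schedule = build_schedule(config, rng)
        records = run_session(
            schedule, agent_factory(params), config, rng, subject_id=f"s{i + 1:02d}"
        )
        frames.append(records_to_frame(records))
    return pd.concat(frames, ignore_index=True)
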