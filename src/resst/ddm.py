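"""Quantile-based fitting of the drift-diffusion model to go RTs.

The decision process is a Wiener diffusion between absorbing boundaries 0
and ``a`` starting at ``z``, with drift ``v`` and within-trial noise
``s = 0.1`` (Ratcliff convention).  Across-trial variability: drift drawn
``N(v, eta)``, starting point uniform on ``z +/- sz/2``, non-decision time
uniform on ``Ter +/- st/2``.  RT = first-passage time + non-decision time.

Predicted RT-quantile bin probabilities come from the classical
large-time series of the defective first-passage CDF, with the
across-trial variabilities integrated by Gaussian quadrature
(Gauss-Hermite for the normal drift, Gauss-Legendre for the uniform
ranges).  Fitting minimizes either the percentile-based chi-square or the
multinomial negative log-likelihood over the bin counts; BIC is always
computed from the multinomial log-likelihood at the optimum.

Three cue-bias model variants are compared: ``both_free`` (z and v vary by
condition), ``v_only`` and ``z_only``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .agents import DDMAgentParams
from .stats import FriedmanResult, friedman

__all__ = [
    "VARIANTS",
    "QuantileData",
    "DDMFitResult",
    "fpt_cdf",
    "absorption_prob_upper",
    "fptd_bins",
    "chi2_objective",
    "multinomial_loglik",
    "quantile_data",
    "fit_subject",
    "compare_models",
    "zscore_params",
    "friedman_on_params",
]

VARIANTS = ("both_free", "v_only", "z_only")
QUANTILE_PROBS = (0.1, 0.3, 0.5, 0.7, 0.9)
_N_QUAD = 11
_P_FLOOR = 1e-10


# ---------------------------------------------------------------------------
# first-passage time distribution
# ---------------------------------------------------------------------------

def absorption_prob_upper(v, a, z, s=0.1):
    """P(hit upper boundary) = (1 - exp(-2vz/s^2)) / (1 - exp(-2va/s^2)).

    Evaluated in overflow-safe form on both drift signs; the zero-drift
    limit is z/a.
    """
    v = np.asarray(v, dtype=float)
    z = np.asarray(z, dtype=float)
    x = 2.0 * v / s**2
    x, z = np.broadcast_arrays(x, z)
    p = np.empty_like(x, dtype=float)
    small = np.abs(x) * a < 1e-9
    pos = (~small) & (x > 0)
    neg = (~small) & (x < 0)
    p[small] = z[small] / a
    p[pos] = np.expm1(-x[pos] * z[pos]) / np.expm1(-x[pos] * a)
    # for negative drift multiply through by exp(x a): all exponents <= 0
    ex = np.exp(x[neg] * a)
    p[neg] = (ex - np.exp(x[neg] * (a - z[neg]))) / (ex - 1.0)
    return p


def _k_terms(t_min, a_tilde):
    """Series length so the truncated tail is < ~1e-10 at the earliest time."""
    k = int(np.ceil(a_tilde / np.pi * np.sqrt(2.0 * 27.0 / max(t_min, 1e-4))))
    return min(max(k, 24), 1200)


def fpt_cdf(t, v, z, a, s=0.1, boundary="lower"):
    """Defective first-passage CDF of the two-boundary Wiener process.

    ``t`` is a 1-D array of decision times (s); ``v`` and ``z`` are node
    arrays of equal length (quadrature nodes).  Returns shape
    ``(len(v), len(t))``; ``F(inf)`` equals the absorption probability of
    the requested boundary.  Computed from the large-time eigenfunction
    series of the transition density integrated in time.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    v = np.atleast_1d(np.asarray(v, dtype=float))
    z = np.broadcast_to(np.atleast_1d(np.asarray(z, dtype=float)), v.shape)
    if boundary == "upper":
        v, z = -v, a - z
    elif boundary != "lower":
        raise ValueError("boundary must be 'lower' or 'upper'")
    vt = v / s
    zt = z / s
    at = a / s

    pos = t > 0
    t_pos = t[pos]
    out = np.zeros((v.size, t.size))
    p_abs = 1.0 - absorption_prob_upper(v, a, z, s=s)  # P(lower) for current (v, z)
    if t_pos.size:
        K = _k_terms(float(t_pos.min()), at)
        k = np.arange(1, K + 1)
        lam = 0.5 * (vt[:, None] ** 2 + (k[None, :] * np.pi / at) ** 2)  # (N, K)
        coef = k[None, :] * np.sin(k[None, :] * np.pi * zt[:, None] / at)  # (N, K)
        pref = (np.pi / at**2) * np.exp(-vt * zt)  # (N,)
        # tail mass beyond t: pref * sum_k coef * exp(-lam t) / lam
        expo = np.exp(-lam[:, :, None] * t_pos[None, None, :])  # (N, K, T)
        tail = pref[:, None] * np.einsum("nk,nkt->nt", coef / lam, expo)
        out[:, pos] = np.clip(p_abs[:, None] - tail, 0.0, 1.0)
    return out


_GAUSS_CACHE: dict = {}


def _gauss(kind: str, n: int):
    key = (kind, n)
    if key not in _GAUSS_CACHE:
        if kind == "hermite":
            _GAUSS_CACHE[key] = np.polynomial.hermite.hermgauss(n)
        else:
            _GAUSS_CACHE[key] = np.polynomial.legendre.leggauss(n)
    return _GAUSS_CACHE[key]


def _quad_nodes(cond_params):
    """Quadrature nodes/weights over (v, z, ter) across-trial variability."""
    v0, z0 = cond_params["v"], cond_params["z"]
    a = cond_params["a"]
    ter0 = cond_params["ter"]
    eta = cond_params.get("eta", 0.0)
    sz = cond_params.get("sz", 0.0)
    st = cond_params.get("st", 0.0)

    def gh():
        x, w = _gauss("hermite", _N_QUAD)
        return v0 + math.sqrt(2.0) * eta * x, w / math.sqrt(math.pi)

    def gl(center, width):
        x, w = _gauss("legendre", _N_QUAD)
        return center + 0.5 * width * x, 0.5 * w  # weights sum to 1

    vs, wv = gh() if eta > 0 else (np.array([v0]), np.array([1.0]))
    zs, wz = gl(z0, sz) if sz > 0 else (np.array([z0]), np.array([1.0]))
    ts, wt = gl(ter0, st) if st > 0 else (np.array([ter0]), np.array([1.0]))
    V, Z, T = np.meshgrid(vs, zs, ts, indexing="ij")
    W = (wv[:, None, None] * wz[None, :, None] * wt[None, None, :]).ravel()
    return V.ravel(), np.clip(Z.ravel(), 1e-6, a - 1e-6), T.ravel(), W


def fptd_bins(cond_params, edges_s, pooled_error: bool = False):
    """Predicted bin probabilities for one condition.

    ``edges_s`` is a dict with keys ``"upper"`` and ``"lower"`` holding the
    interior RT quantile edges (seconds) of each response; with
    ``pooled_error`` the lower boundary contributes one pooled bin.
    Returns ``(p_upper, p_lower)`` whose concatenation sums to 1 (within
    series/quadrature tolerance).
    """
    a, s = cond_params["a"], cond_params.get("s", 0.1)
    v, z, ter, w = _quad_nodes(cond_params)

    def bins(boundary, edges):
        p_inf = (
            absorption_prob_upper(v, a, z, s=s)
            if boundary == "upper"
            else 1.0 - absorption_prob_upper(v, a, z, s=s)
        )
        p_inf = w @ p_inf
        if edges is None or len(edges) == 0:
            return np.array([p_inf])
        # decision-time edges differ only with the non-decision-time node
        e = np.asarray(edges, dtype=float)
        cdf = np.zeros(e.size)
        for tval in np.unique(ter):
            sel = ter == tval
            cdf_nodes = fpt_cdf(e - tval, v[sel], z[sel], a, s, boundary)
            cdf += w[sel] @ cdf_nodes
        cdf = np.concatenate(([0.0], np.maximum.accumulate(cdf), [max(p_inf, cdf.max())]))
        return np.diff(cdf)

    p_up = bins("upper", edges_s.get("upper"))
    p_lo = bins("lower", None if pooled_error else edges_s.get("lower"))
    return p_up, p_lo


# ---------------------------------------------------------------------------
# observed quantile data and objectives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuantileData:
    """Observed RT-quantile bin structure for one condition."""

    condition: str
    edges: dict  # "upper"/"lower" -> interior quantile edges (s) or None
    counts: dict  # "upper"/"lower" -> bin counts
    n_total: int
    pooled_error: bool


def _response_bins(rts_s, probs):
    edges = np.quantile(rts_s, probs)
    counts = np.histogram(rts_s, np.concatenate(([0.0], edges, [np.inf])))[0]
    return edges, counts


def quantile_data(
    trials: pd.DataFrame,
    condition: str,
    probs=QUANTILE_PROBS,
    min_errors: int = 5,
) -> QuantileData:
    """Bin the go RTs of one condition by response-conditional quantiles.

    Correct responses (upper boundary) always get the full quantile bin
    set; error responses get their own quantile bins only when at least
    ``min_errors`` are available, otherwise a single pooled error bin.
    Omissions are excluded (the diffusion models committed responses).
    """
    go = trials[(trials["condition"] == condition) & (trials["trial_type"] == "go")]
    correct = go.loc[go["outcome"] == "correct_go", "rt_ms"].dropna().to_numpy() / 1e3
    errors = go.loc[go["outcome"] == "failed_go_wrongkey", "rt_ms"].dropna().to_numpy() / 1e3
    if correct.size < 2:
        raise ValueError(f"too few correct go RTs in condition {condition!r}")
    e_up, c_up = _response_bins(correct, probs)
    pooled = errors.size < min_errors
    if pooled:
        edges = {"upper": e_up, "lower": None}
        counts = {"upper": c_up, "lower": np.array([errors.size])}
    else:
        e_lo, c_lo = _response_bins(errors, probs)
        edges = {"upper": e_up, "lower": e_lo}
        counts = {"upper": c_up, "lower": c_lo}
    return QuantileData(
        condition=condition,
        edges=edges,
        counts=counts,
        n_total=int(correct.size + errors.size),
        pooled_error=pooled,
    )


def chi2_objective(observed: QuantileData, p_upper, p_lower) -> float:
    """Pearson chi-square over the quantile bins, predictions floored."""
    if observed.n_total == 0:
        raise ValueError("empty condition")
    o = np.concatenate([observed.counts["upper"], observed.counts["lower"]])
    p = np.maximum(np.concatenate([p_upper, p_lower]), _P_FLOOR)
    e = observed.n_total * p
    return float(((o - e) ** 2 / e).sum())


def multinomial_loglik(observed: QuantileData, p_upper, p_lower) -> float:
    """Multinomial log-likelihood sum(O * ln p) over the quantile bins."""
    if observed.n_total == 0:
        raise ValueError("empty condition")
    o = np.concatenate([observed.counts["upper"], observed.counts["lower"]])
    p = np.maximum(np.concatenate([p_upper, p_lower]), _P_FLOOR)
    p = p / p.sum()
    return float((o * np.log(p)).sum())


# ---------------------------------------------------------------------------
# model variants and fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DDMFitResult:
    params: DDMAgentParams
    variant: str
    objective: str
    objective_value: float
    loglik: float
    bic: float
    n_free: int
    n_total: int
    converged: bool
    n_restarts_used: int


def _n_free(variant: str, conditions, fit_sz_st: bool) -> int:
    k = len(conditions)
    base = 3  # a, ter, eta
    if fit_sz_st:
        base += 2
    if variant == "both_free":
        return base + 2 * k
    if variant in ("v_only", "z_only"):
        return base + k + 1
    raise ValueError(f"unknown variant {variant!r}")


def _unpack(theta, variant, conditions, fit_sz_st):
    k = len(conditions)
    i = 0
    a = math.exp(theta[i]); i += 1
    ter = math.exp(theta[i]); i += 1
    eta = math.exp(theta[i]); i += 1
    sz = st = 0.0
    if fit_sz_st:
        sz = math.exp(theta[i]); i += 1
        st = math.exp(theta[i]); i += 1
    if variant in ("both_free", "z_only"):
        w = 1.0 / (1.0 + np.exp(-theta[i:i + k])); i += k
    else:
        w = np.full(k, 1.0 / (1.0 + math.exp(-theta[i]))); i += 1
    if variant in ("both_free", "v_only"):
        v = np.asarray(theta[i:i + k], dtype=float); i += k
    else:
        v = np.full(k, float(theta[i])); i += 1
    z = {c: float(w[j] * a) for j, c in enumerate(conditions)}
    vv = {c: float(v[j]) for j, c in enumerate(conditions)}
    return {"a": a, "ter": ter, "eta": eta, "sz": sz, "st": st, "z": z, "v": vv}


def _pack_init(init, variant, conditions, fit_sz_st):
    theta = [math.log(init["a"]), math.log(init["ter"]), math.log(max(init["eta"], 1e-3))]
    if fit_sz_st:
        theta += [math.log(max(init["sz"], 1e-3)), math.log(max(init["st"], 1e-3))]
    w0 = np.clip(np.array([init["z"][c] / init["a"] for c in conditions]), 0.05, 0.95)
    logit = np.log(w0 / (1 - w0))
    if variant in ("both_free", "z_only"):
        theta += list(logit)
    else:
        theta += [float(logit.mean())]
    v0 = np.array([init["v"][c] for c in conditions])
    if variant in ("both_free", "v_only"):
        theta += list(v0)
    else:
        theta += [float(v0.mean())]
    return np.array(theta)


def _moment_init(qdata, conditions, s=0.1):
    """EZ-style moment initialization for a shared starting point a/2."""
    accs, mrts, vrts = [], [], []
    for c in conditions:
        q = qdata[c]
        n_up = q.counts["upper"].sum()
        accs.append(max(min(n_up / q.n_total, 0.97), 0.55))
        med = q.edges["upper"][len(q.edges["upper"]) // 2]
        iqr = q.edges["upper"][-2] - q.edges["upper"][1]
        mrts.append(med)
        vrts.append(max((iqr / 1.35) ** 2, 1e-4))
    pc, vrt = float(np.mean(accs)), float(np.mean(vrts))
    y = math.log(pc / (1 - pc))
    # EZ-diffusion drift and boundary (Wagenmakers et al. convention)
    x = y * (y * pc**2 - y * pc + pc - 0.5) / vrt
    v = math.copysign(s * x**0.25, y) if x > 0 else 0.2
    a = s**2 * y / max(v, 1e-3)
    a = min(max(a, 0.06), 0.4)
    v = min(max(v, 0.05), 0.6)
    mdt = (a / (2 * v)) * math.tanh(v * a / s**2)
    ter = max(float(np.mean(mrts)) - mdt, 0.05)
    return {
        "a": a,
        "ter": ter,
        "eta": 0.1,
        "sz": 0.05 * a,
        "st": 0.05,
        "z": {c: a / 2 for c in conditions},
        "v": {c: v for c in conditions},
    }


def fit_subject(
    trials: pd.DataFrame,
    variant: str = "z_only",
    objective: str = "chi2",
    n_restarts: int = 5,
    rng=None,
    conditions=None,
    fit_sz_st: bool = False,
    maxiter: int = 800,
    min_go_trials: int = 50,
) -> DDMFitResult:
    """Joint quantile fit of one subject's go RTs across conditions.

    Parameters ``a``, ``Ter`` and ``eta`` are shared across conditions;
    ``z`` and/or ``v`` vary with the cue condition according to the model
    variant.  Nelder-Mead is run from a moment-based initial point plus
    ``n_restarts - 1`` seeded perturbations; the best run is kept.  The BIC
    is computed from the multinomial log-likelihood at the optimum
    (regardless of the search objective), with the total trial count as N.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if objective not in ("chi2", "multinomial"):
        raise ValueError("objective must be 'chi2' or 'multinomial'")
    if rng is None:
        rng = np.random.default_rng()
    if conditions is None:
        conditions = sorted(trials["condition"].unique())
    qdata = {c: quantile_data(trials, c) for c in conditions}
    for c in conditions:
        n_go = int(qdata[c].n_total)
        if n_go < min_go_trials:
            import warnings

            warnings.warn(f"condition {c}: only {n_go} go RTs; fit may be unstable")

    def predicted(par):
        out = {}
        for c in conditions:
            cp = {
                "a": par["a"], "ter": par["ter"], "eta": par["eta"],
                "sz": par["sz"], "st": par["st"], "z": par["z"][c], "v": par["v"][c],
            }
            out[c] = fptd_bins(cp, qdata[c].edges, pooled_error=qdata[c].pooled_error)
        return out

    def objective_fn(theta):
        par = _unpack(theta, variant, conditions, fit_sz_st)
        if par["a"] > 1.0 or par["ter"] > 3.0 or par["eta"] > 1.0:
            return 1e10
        try:
            pred = predicted(par)
        except (ValueError, FloatingPointError):
            return 1e10
        total = 0.0
        for c in conditions:
            pu, pl = pred[c]
            if objective == "chi2":
                total += chi2_objective(qdata[c], pu, pl)
            else:
                total -= multinomial_loglik(qdata[c], pu, pl)
        return total if math.isfinite(total) else 1e10

    init = _moment_init(qdata, conditions)
    theta0 = _pack_init(init, variant, conditions, fit_sz_st)
    best = None
    converged = False
    used = 0
    for r in range(n_restarts):
        start = theta0 if r == 0 else theta0 + rng.normal(0.0, 0.25, size=theta0.size)
        res = minimize(
            objective_fn,
            start,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-4},
        )
        used = r + 1
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)

    par = _unpack(best.x, variant, conditions, fit_sz_st)
    pred = predicted(par)
    loglik = sum(
        multinomial_loglik(qdata[c], *pred[c]) for c in conditions
    )
    n_total = sum(qdata[c].n_total for c in conditions)
    m = _n_free(variant, conditions, fit_sz_st)
    bic = -2.0 * loglik + m * math.log(n_total)
    params = DDMAgentParams(
        a=par["a"], z=par["z"], v=par["v"], ter=par["ter"],
        sz=par["sz"], st=par["st"], eta=par["eta"],
    )
    return DDMFitResult(
        params=params,
        variant=variant,
        objective=objective,
        objective_value=float(best.fun),
        loglik=float(loglik),
        bic=float(bic),
        n_free=m,
        n_total=n_total,
        converged=converged,
        n_restarts_used=used,
    )


# ---------------------------------------------------------------------------
# model comparison across subjects
# ---------------------------------------------------------------------------

def compare_models(fits: dict) -> dict:
    """Per-subject best variant (argmin BIC) and cohort BIC sums.

    ``fits`` maps subject_id -> {variant -> DDMFitResult}; every subject
    must carry every variant.
    """
    variants = None
    best = {}
    sums: dict = {}
    for sid, by_variant in fits.items():
        if variants is None:
            variants = sorted(by_variant)
        if sorted(by_variant) != variants:
            raise ValueError(f"subject {sid}: missing model variants")
        best[sid] = min(by_variant, key=lambda v: by_variant[v].bic)
        for v, fit in by_variant.items():
            sums[v] = sums.get(v, 0.0) + fit.bic
    counts = {v: sum(1 for b in best.values() if b == v) for v in variants}
    return {"best_by_subject": best, "selection_counts": counts, "bic_sums": sums}


def _param_matrix(fits_one_variant: dict, parameter: str) -> pd.DataFrame:
    rows = {}
    for sid, fit in fits_one_variant.items():
        vals = getattr(fit.params, parameter)
        rows[sid] = dict(vals)
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def zscore_params(fits_one_variant: dict, parameter: str = "z") -> pd.DataFrame:
    """Across-subject z-scores of a per-condition parameter (z or v)."""
    mat = _param_matrix(fits_one_variant, parameter)
    sd = mat.std(axis=0, ddof=1)
    out = (mat - mat.mean(axis=0)) / sd.replace(0.0, np.nan)
    return out.fillna(0.0)


def friedman_on_params(fits_one_variant: dict, parameter: str = "z"):
    """Friedman test on the subjects x conditions parameter matrix.

    Returns None when the parameter is shared across conditions in the
    fitted variant (no between-condition variation to test).
    """
    mat = _param_matrix(fits_one_variant, parameter)
    m = mat.to_numpy()
    if np.allclose(m, m[:, [0]]):
        return None
    return friedman(mat)
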