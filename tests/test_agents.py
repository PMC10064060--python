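import numpy as np
import pytest
from scipy import stats as sps

import resst
from resst.agents import (
    DEFAULT_DDM_TEMPLATE,
    DEFAULT_HETEROGENEITY,
    DEFAULT_TEMPLATE,
    CohortSpec,
    DDMAgentParams,
    RaceAgentParams,
    ddm_sample,
    ddm_sample_coupled,
    ddm_trial,
    make_cohort,
    race_trial,
)
from resst.ddm import absorption_prob_upper
from resst.metrics import cohort_table

CONDS = ("Gplus", "Neutral", "Splus")


def _flat_params(mu=500.0, sigma=50.0, tau=100.0, ssrt=230.0, **kw):
    return RaceAgentParams(
        mu={c: mu for c in CONDS},
        sigma={c: sigma for c in CONDS},
        tau={c: tau for c in CONDS},
        ssrt={c: ssrt for c in CONDS},
        **kw,
    )


class TestRaceTrial:
    def test_go_always_wins_huge_ssd(self):
        rng = np.random.default_rng(0)
        p = _flat_params()
        for _ in range(50):
            responded, rt, _ = race_trial(p, "Neutral", "stop", 1e6, rng)
            assert responded and rt > 0

    def test_stop_always_wins_zero_ssrt_zero_ssd(self):
        rng = np.random.default_rng(0)
        p = _flat_params(ssrt=1e-9)
        for _ in range(50):
            responded, rt, _ = race_trial(p, "Neutral", "stop", 0.0, rng)
            assert not responded

    def test_p_respond_crosses_half_at_analytic_ssd(self):
        # p(respond | ssd) = F_exG(ssd + ssrt); at the SSD where the
        # analytic CDF crosses 0.5 the Monte-Carlo estimate must sit in
        # [0.48, 0.52], and p(respond) must be nondecreasing in SSD.
        mu, sigma, tau, ssrt = 500.0, 50.0, 100.0, 230.0
        p = _flat_params(mu, sigma, tau, ssrt)
        dist = sps.exponnorm(K=tau / sigma, loc=mu, scale=sigma)
        s_star = dist.ppf(0.5) - ssrt
        rng = np.random.default_rng(1)
        n = 100_000

        def p_mc(ssd):
            hits = sum(
                race_trial(p, "Gplus", "stop", ssd, rng)[0] for _ in range(n)
            )
            return hits / n

        p_half = p_mc(s_star)
        assert 0.48 <= p_half <= 0.52
        lo, hi = p_mc(s_star - 150), p_mc(s_star + 150)
        assert lo < p_half < hi

    def test_context_independence(self):
        # the go finish-time law on stop trials equals the go-trial law:
        # with an SSD so large that every go process wins, the stop-trial
        # RT sample must be indistinguishable from the go-trial sample
        p = _flat_params()
        rng = np.random.default_rng(2)
        n = 20_000
        go = np.array([race_trial(p, "Gplus", "go", None, rng)[1] for _ in range(n)])
        stop = np.array(
            [race_trial(p, "Gplus", "stop", 1e9, rng)[1] for _ in range(n)]
        )
        assert sps.ks_2samp(go, stop).pvalue > 0.01

    def test_failed_stop_rts_faster_than_go(self):
        # censoring theorem of the independent race
        p = _flat_params()
        rng = np.random.default_rng(3)
        go, failed = [], []
        for _ in range(20_000):
            _, rt, _ = race_trial(p, "Gplus", "go", None, rng)
            go.append(rt)
            responded, rt, _ = race_trial(p, "Gplus", "stop", 350.0, rng)
            if responded:
                failed.append(rt)
        assert np.mean(failed) < np.mean(go)

    def test_invalid_inputs(self):
        p = _flat_params()
        rng = np.random.default_rng(0)
        with pytest.raises(KeyError):
            race_trial(p, "Xplus", "go", None, rng)
        with pytest.raises(ValueError):
            race_trial(p, "Gplus", "go", 300.0, rng)
        with pytest.raises(ValueError):
            _flat_params(sigma=0.0)


class TestDDMAgent:
    def test_symmetric_absorption(self):
        p = DDMAgentParams(a=0.16, z={"Neutral": 0.08}, v={"Neutral": 0.0}, ter=0.3)
        ch, _ = ddm_sample(p, "Neutral", 30_000, np.random.default_rng(4))
        pu = (ch == 1).mean()
        assert abs(pu - 0.5) < 3 * np.sqrt(0.25 / 30_000)

    def test_absorption_matches_closed_form(self):
        v, a, z = 0.25, 0.16, 0.08
        p = DDMAgentParams(a=a, z={"Neutral": z}, v={"Neutral": v}, ter=0.3)
        ch, _ = ddm_sample(p, "Neutral", 30_000, np.random.default_rng(5))
        target = float(absorption_prob_upper(v, a, z))
        se = np.sqrt(target * (1 - target) / 30_000)
        assert abs((ch == 1).mean() - target) < 3 * se

    def test_starting_point_ordering_orders_mean_rt(self):
        rng = np.random.default_rng(6)
        means = {}
        for cond in CONDS:
            ch, rt = ddm_sample(DEFAULT_DDM_TEMPLATE, cond, 3000, rng)
            means[cond] = np.nanmean(rt[ch == 1])
        assert means["Gplus"] < means["Neutral"] < means["Splus"]

    def test_halving_step_size_leaves_quantiles(self):
        # strong-convergence check: the same Brownian paths stepped at dt
        # and dt/2 must give RT quantiles within 1 ms
        cc, rc, cf, rf = ddm_sample_coupled(
            DEFAULT_DDM_TEMPLATE, "Neutral", 30_000, np.random.default_rng(7)
        )
        ok = (cc == 1) & (cf == 1)
        qs = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        dq = np.quantile(rc[ok], qs) - np.quantile(rf[ok], qs)
        assert np.max(np.abs(dq)) < 1.0
        assert (cc[(cc != 0) & (cf != 0)] == cf[(cc != 0) & (cf != 0)]).mean() > 0.995

    def test_ddm_trial_units(self):
        choice, rt = ddm_trial(DEFAULT_DDM_TEMPLATE, "Neutral", np.random.default_rng(8))
        assert choice in ("upper", "lower")
        assert 200.0 < rt < 6000.0  # milliseconds

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            DDMAgentParams(a=0.1, z={"Neutral": 0.12}, v={"Neutral": 0.2}, ter=0.3)
        with pytest.raises(ValueError):
            DDMAgentParams(a=0.1, z={"Neutral": 0.05}, v={"Neutral": 0.2}, ter=0.1, st=0.3)


class TestCohort:
    def test_zero_heterogeneity_clones_template(self):
        params = make_cohort(CohortSpec(3, DEFAULT_TEMPLATE, {}, seed=0))
        assert all(p == DEFAULT_TEMPLATE for p in params)

    def test_default_cohort_matches_study_pattern(self, default_cohort_summaries):
        rt = cohort_table(default_cohort_summaries, "mean_rt_ms").mean(axis=0)
        assert rt["Gplus"] < rt["Neutral"] < rt["Splus"]
        for cond, target in (("Gplus", 619), ("Neutral", 652), ("Splus", 686)):
            assert abs(rt[cond] - target) <= 25
        ssrt = cohort_table(default_cohort_summaries, "ssrt_ms").mean(axis=0)
        for cond, target in (("Gplus", 230), ("Neutral", 253), ("Splus", 230)):
            assert abs(ssrt[cond] - target) <= 20

    def test_p_respond_window_mostly_satisfied(self, default_cohort_summaries):
        pr = cohort_table(default_cohort_summaries, "p_respond")
        ok = ((pr >= 0.35) & (pr <= 0.65)).all(axis=1).sum()
        assert ok >= 13

    def test_resampling_respects_invariants(self):
        # heterogeneity wide enough that raw draws often violate sigma > 0:
        # resampling must still deliver only valid parameter sets
        params = make_cohort(CohortSpec(20, DEFAULT_TEMPLATE, {"sigma": 100.0}, seed=0))
        assert len(params) == 20
        for p in params:
            assert all(s > 0 for s in p.sigma.values())
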