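import numpy as np
import pytest

from resst.agents import DDMAgentParams, ddm_sample
from resst.ddm import (
    QUANTILE_PROBS,
    QuantileData,
    absorption_prob_upper,
    chi2_objective,
    compare_models,
    fit_subject,
    fpt_cdf,
    fptd_bins,
    friedman_on_params,
    multinomial_loglik,
    quantile_data,
    zscore_params,
)

from .conftest import make_ddm_trials

A, S = 0.16, 0.1


def _cp(v=0.25, z=0.08, ter=0.3, eta=0.0, sz=0.0, st=0.0):
    return {"a": A, "s": S, "v": v, "z": z, "ter": ter, "eta": eta, "sz": sz, "st": st}


class TestFirstPassage:
    def test_symmetric_split(self):
        up = fpt_cdf(np.array([50.0]), np.array([0.0]), np.array([A / 2]), A, S, "upper")
        assert up[0, 0] == pytest.approx(0.5, abs=1e-6)

    def test_matches_closed_form_absorption(self):
        for v, z in [(0.25, 0.08), (-0.15, 0.05), (0.4, 0.12), (0.0, 0.03)]:
            series = fpt_cdf(np.array([60.0]), np.array([v]), np.array([z]), A, S, "upper")
            assert series[0, 0] == pytest.approx(
                float(absorption_prob_upper(v, A, z, S)), abs=1e-6
            )

    def test_defective_masses_sum_to_one(self):
        edges = {"upper": np.array([0.4, 0.5, 0.6, 0.7, 0.9]),
                 "lower": np.array([0.4, 0.5, 0.6, 0.7, 0.9])}
        for kw in ({}, {"eta": 0.1}, {"eta": 0.08, "sz": 0.02, "st": 0.1}):
            pu, pl = fptd_bins(_cp(**kw), edges)
            assert pu.sum() + pl.sum() == pytest.approx(1.0, abs=1e-6)

    def test_quadrature_refinement_stable(self):
        from resst import ddm as D

        edges = {"upper": np.array([0.45, 0.55, 0.62, 0.7, 0.85]), "lower": None}
        cp = _cp(eta=0.08, sz=0.02, st=0.1)
        coarse = fptd_bins(cp, edges, pooled_error=True)
        old = D._N_QUAD
        try:
            D._N_QUAD = 16
            fine = fptd_bins(cp, edges, pooled_error=True)
        finally:
            D._N_QUAD = old
        for c, f in zip(coarse, fine):
            assert np.max(np.abs(c - f)) < 1e-4

    def test_bins_match_simulator(self):
        # dual route: analytic quadrature vs Euler simulation
        params = DDMAgentParams(
            a=A, z={"Neutral": 0.08}, v={"Neutral": 0.25}, ter=0.3, eta=0.08
        )
        rng = np.random.default_rng(11)
        n = 30_000
        ch, rt = ddm_sample(params, "Neutral", n, rng)
        rt_s = rt / 1e3
        edges = np.quantile(rt_s[ch == 1], QUANTILE_PROBS)
        pu, pl = fptd_bins(
            _cp(eta=0.08), {"upper": edges, "lower": None}, pooled_error=True
        )
        counts = np.histogram(rt_s[ch == 1], np.concatenate(([0], edges, [np.inf])))[0]
        obs = np.concatenate([counts, [np.sum(ch == -1)]]) / n
        pred = np.concatenate([pu, pl])
        se = np.sqrt(pred * (1 - pred) / n)
        assert np.all(np.abs(obs - pred) < 3 * se + 1e-9)


class TestObjectives:
    def _toy(self, counts):
        return QuantileData(
            condition="Neutral",
            edges={"upper": None, "lower": None},
            counts={"upper": np.array(counts[:1]), "lower": np.array(counts[1:])},
            n_total=int(sum(counts)),
            pooled_error=True,
        )

    def test_chi2_hand_arithmetic(self):
        # O = (3, 7), p = (.5, .5), N = 10 -> (3-5)^2/5 + (7-5)^2/5 = 1.6
        q = self._toy([3, 7])
        assert chi2_objective(q, np.array([0.5]), np.array([0.5])) == pytest.approx(1.6)

    def test_chi2_zero_at_expected_counts(self):
        q = self._toy([4, 6])
        assert chi2_objective(q, np.array([0.4]), np.array([0.6])) == pytest.approx(0.0)

    def test_loglik_maximized_at_empirical_proportions(self):
        q = self._toy([3, 7])
        best = multinomial_loglik(q, np.array([0.3]), np.array([0.7]))
        for p in (0.1, 0.2, 0.4, 0.5, 0.8):
            assert multinomial_loglik(q, np.array([p]), np.array([1 - p])) <= best


TRUTH = DDMAgentParams(
    a=0.16,
    z={"Gplus": 0.096, "Neutral": 0.080, "Splus": 0.064},
    v={c: 0.25 for c in ("Gplus", "Neutral", "Splus")},
    ter=0.30,
    eta=0.08,
)


class TestFitting:
    def test_objective_at_truth_beats_perturbed_truth(self):
        trials = make_ddm_trials(TRUTH, 5000, 21)
        qd = {c: quantile_data(trials, c) for c in ("Gplus", "Neutral", "Splus")}

        def chi2_at(params):
            total = 0.0
            for c, q in qd.items():
                cp = {"a": params.a, "s": 0.1, "ter": params.ter, "eta": params.eta,
                      "sz": params.sz, "st": params.st, "z": params.z[c], "v": params.v[c]}
                pu, pl = fptd_bins(cp, q.edges, pooled_error=q.pooled_error)
                total += chi2_objective(q, pu, pl)
            return total

        base = chi2_at(TRUTH)
        worse = DDMAgentParams(
            a=TRUTH.a * 1.1,
            z={k: v * 1.1 for k, v in TRUTH.z.items()},
            v={k: v * 1.1 for k, v in TRUTH.v.items()},
            ter=TRUTH.ter * 1.1,
            eta=TRUTH.eta * 1.1,
        )
        assert base <= chi2_at(worse)

    def test_null_data_gives_similar_starting_points(self):
        # all conditions identical: the both_free fit must not invent a bias
        null = DDMAgentParams(
            a=0.16, z={c: 0.08 for c in ("Gplus", "Neutral", "Splus")},
            v={c: 0.25 for c in ("Gplus", "Neutral", "Splus")}, ter=0.30, eta=0.08,
        )
        trials = make_ddm_trials(null, 500, 22)
        fit = fit_subject(trials, "both_free", n_restarts=3, rng=np.random.default_rng(0))
        zs = list(fit.params.z.values())
        assert max(zs) - min(zs) < 0.1 * fit.params.a

    def test_z_only_fit_recovers_parameters(self):
        trials = make_ddm_trials(TRUTH, 500, 23)
        fit = fit_subject(trials, "z_only", n_restarts=3, rng=np.random.default_rng(1))
        # the cue-bias structure is what the fit must recover; a/eta/v trade
        # off along a ridge at this trial count, so only loose bounds there
        assert fit.params.z["Gplus"] > fit.params.z["Neutral"] > fit.params.z["Splus"]
        assert abs(fit.params.a - TRUTH.a) < 0.06
        assert abs(fit.params.ter - TRUTH.ter) < 0.08
        # BIC bookkeeping: -2 lnL + m ln N
        assert fit.bic == pytest.approx(
            -2 * fit.loglik + fit.n_free * np.log(fit.n_total)
        )

    def test_variant_errors(self):
        trials = make_ddm_trials(TRUTH, 200, 24)
        with pytest.raises(ValueError):
            fit_subject(trials, "no_such_variant")
        with pytest.raises(ValueError):
            fit_subject(trials, "z_only", objective="huber")


class TestComparison:
    def _fake_fit(self, z_vals, bic, variant="z_only"):
        from resst.ddm import DDMFitResult

        params = DDMAgentParams(
            a=0.16, z=dict(z_vals), v={c: 0.25 for c in z_vals}, ter=0.3, eta=0.05
        )
        return DDMFitResult(
            params=params, variant=variant, objective="chi2", objective_value=1.0,
            loglik=-1.0, bic=bic, n_free=7, n_total=1000, converged=True,
            n_restarts_used=1,
        )

    def test_selection_counts_and_sums(self):
        z = {"Gplus": 0.09, "Neutral": 0.08, "Splus": 0.07}
        fits = {
            "s1": {"z_only": self._fake_fit(z, 100.0), "v_only": self._fake_fit(z, 110.0)},
            "s2": {"z_only": self._fake_fit(z, 105.0), "v_only": self._fake_fit(z, 101.0)},
        }
        comp = compare_models(fits)
        assert comp["best_by_subject"] == {"s1": "z_only", "s2": "v_only"}
        assert comp["selection_counts"] == {"z_only": 1, "v_only": 1}
        assert comp["bic_sums"]["z_only"] == pytest.approx(205.0)

    def test_missing_variant_rejected(self):
        z = {"Gplus": 0.09, "Neutral": 0.08, "Splus": 0.07}
        fits = {
            "s1": {"z_only": self._fake_fit(z, 100.0), "v_only": self._fake_fit(z, 110.0)},
            "s2": {"z_only": self._fake_fit(z, 105.0)},
        }
        with pytest.raises(ValueError):
            compare_models(fits)

    def test_zscores_zero_for_identical_subjects(self):
        z = {"Gplus": 0.09, "Neutral": 0.08, "Splus": 0.07}
        fits = {f"s{i}": self._fake_fit(z, 100.0) for i in range(5)}
        assert (zscore_params(fits, "z").to_numpy() == 0).all()

    def test_friedman_undefined_for_shared_parameter(self):
        z = {"Gplus": 0.09, "Neutral": 0.08, "Splus": 0.07}
        fits = {f"s{i}": self._fake_fit(z, 100.0) for i in range(5)}
        assert friedman_on_params(fits, "v") is None  # v shared across conditions
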