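"""Unit and property tests for the BMA-CRM posterior engine."""

import math

import numpy as np
import pytest
from scipy.integrate import simpson
from scipy.special import xlog1py, xlogy
from scipy.stats import norm

from conftest import random_tally
from phaseone.crm import (
    DoseDecision,
    QuadratureSpec,
    Skeleton,
    ToxicityTally,
    bma_toxicity_estimates,
    log_likelihood,
    log_marginal_likelihood,
    model_weights,
    next_dose,
    overdose_probability_lowest_dose,
    posterior_alpha_mean,
    select_mtd,
    should_terminate,
    toxicity_probability,
    _closest_to_target,
)

SK1 = Skeleton((0.05, 0.10, 0.20))
SK2 = Skeleton((0.08, 0.20, 0.40))
SD = math.sqrt(2.0)


def dense_oracle(skeleton, tally, prior_sd=SD, nodes=200_001, moment="mean"):
    """Independent dense-grid Simpson quadrature of the alpha posterior."""
    g = np.linspace(-12 * prior_sd, 12 * prior_sd, nodes)
    p = np.asarray(skeleton.probabilities)
    n = np.asarray(tally.n, dtype=float)
    y = np.asarray(tally.y, dtype=float)
    pi = p[None, :] ** np.exp(g)[:, None]
    ll = (xlogy(y, pi) + xlog1py(n - y, -pi)).sum(axis=1)
    dens = np.exp(ll) * norm.pdf(g, 0, prior_sd)
    z = simpson(dens, x=g)
    if moment == "mean":
        return simpson(g * dens, x=g) / z
    if moment == "logz":
        return float(np.log(z))
    raise ValueError(moment)


class TestToxicityProbability:
    def test_identity_at_alpha_zero(self):
        assert toxicity_probability(0.0, 0.05) == 0.05

    def test_limits_and_monotonicity(self):
        assert toxicity_probability(20.0, 0.05) == pytest.approx(0.0, abs=1e-12)
        assert toxicity_probability(-20.0, 0.05) == pytest.approx(1.0, abs=1e-6)
        alphas = np.linspace(-3, 3, 25)
        vals = [toxicity_probability(a, 0.05) for a in alphas]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_exact_power(self):
        assert toxicity_probability(math.log(2.0), 0.2) == pytest.approx(0.04, rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            toxicity_probability(0.0, bad)


class TestLogLikelihood:
    def test_empty_tally_is_zero(self):
        assert log_likelihood(1.7, SK1, ToxicityTally.empty(3)) == 0.0

    def test_single_nontoxic_patient(self):
        t = ToxicityTally((1, 0, 0), (0, 0, 0))
        assert log_likelihood(0.0, SK1, t) == pytest.approx(math.log(0.95), rel=1e-12)

    def test_against_direct_product_oracle(self):
        # frozen from an independent direct-product evaluation
        t = ToxicityTally((3, 3, 7), (0, 0, 1))
        assert log_likelihood(0.3, SK2, t) == pytest.approx(-3.7578927746068467, rel=1e-12)

    def test_vectorised_matches_scalar(self):
        t = ToxicityTally((2, 1, 0), (1, 0, 0))
        grid = np.array([-1.0, 0.0, 0.5])
        vec = log_likelihood(grid, SK1, t)
        assert vec == pytest.approx([log_likelihood(a, SK1, t) for a in grid])


class TestPosteriorQuadrature:
    def test_empty_tally_mean_is_zero(self):
        assert posterior_alpha_mean(SK1, ToxicityTally.empty(3)) == pytest.approx(0.0, abs=1e-12)

    def test_mean_matches_dense_grid_oracle(self):
        t = ToxicityTally((1, 0, 0), (0, 0, 0))
        # frozen oracle value: 0.38221350741493226
        assert posterior_alpha_mean(SK1, t) == pytest.approx(0.3822135074, abs=1e-7)
        assert dense_oracle(SK1, t) == pytest.approx(0.3822135074, abs=1e-9)

    def test_mean_matches_monte_carlo_sampler(self):
        t = ToxicityTally((3, 3, 7), (0, 0, 1))
        rng = np.random.default_rng(7)
        draws = rng.normal(0, SD, 500_000)
        w = np.exp(log_likelihood(draws, SK2, t))
        mc = float((draws * w).sum() / w.sum())
        se = float(np.std(draws * w / w.mean()) / math.sqrt(len(draws)))
        assert posterior_alpha_mean(SK2, t) == pytest.approx(mc, abs=3 * se)

    def test_log_marginal_empty_tally_zero(self):
        assert log_marginal_likelihood(SK1, ToxicityTally.empty(3)) == pytest.approx(0.0, abs=1e-12)

    def test_log_marginal_matches_dense_grid_oracle(self):
        t = ToxicityTally((1, 0, 0), (0, 0, 0))
        # frozen oracle value: -0.20759078303700362
        assert log_marginal_likelihood(SK1, t) == pytest.approx(-0.2075907830, abs=1e-7)
        assert dense_oracle(SK1, t, moment="logz") == pytest.approx(-0.2075907830, abs=1e-9)

    @pytest.mark.parametrize("tally", [
        ToxicityTally((1, 0, 0), (0, 0, 0)),
        ToxicityTally((3, 3, 7), (0, 0, 1)),
        ToxicityTally((6, 0, 0), (6, 0, 0)),
    ])
    def test_node_doubling_converges(self, model, tally):
        coarse = model
        fine = model.replace(quadrature=QuadratureSpec(nodes=2 * 8192 + 1))
        a1 = posterior_alpha_mean(SK1, tally, quad=coarse.quadrature)
        a2 = posterior_alpha_mean(SK1, tally, quad=fine.quadrature)
        assert abs(a1 - a2) < 1e-6
        s1 = bma_toxicity_estimates(coarse, tally)
        s2 = bma_toxicity_estimates(fine, tally)
        assert np.allclose(s1.pi_hat, s2.pi_hat, atol=1e-6)
        assert abs(s1.p_lowest_overdose - s2.p_lowest_overdose) < 1e-6


class TestModelWeights:
    def test_uniform_prior_empty_tally(self, model):
        w = model_weights(model, ToxicityTally.empty(3))
        assert w == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_identical_skeletons_symmetric(self, model):
        m = model.replace(skeletons=(SK1, SK1))
        w = model_weights(m, ToxicityTally((3, 2, 1), (1, 1, 0)))
        assert w == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_dlt_at_top_dose_matches_dense_oracle(self, model):
        t = ToxicityTally((0, 0, 1), (0, 0, 1))
        lz1 = dense_oracle(SK1, t, moment="logz")
        lz2 = dense_oracle(SK2, t, moment="logz")
        expect = np.exp([lz1, lz2]) / (np.exp(lz1) + np.exp(lz2))
        assert model_weights(model, t) == pytest.approx(expect, abs=1e-7)

    def test_sum_to_one_on_random_tallies(self, fast_model, rng):
        for _ in range(25):
            t = random_tally(rng)
            w = model_weights(fast_model, t)
            assert w.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.all((w >= 0) & (w <= 1))


class TestBmaEstimates:
    def test_prior_estimates_are_skeleton_average(self, model):
        s = bma_toxicity_estimates(model, ToxicityTally.empty(3))
        assert s.pi_hat == pytest.approx([0.065, 0.15, 0.3], abs=1e-12)
        assert s.alpha_hat == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_single_skeleton_prior_is_skeleton(self, single_skeleton_model):
        s = bma_toxicity_estimates(single_skeleton_model, ToxicityTally.empty(3))
        assert s.pi_hat == pytest.approx([0.05, 0.10, 0.20], abs=1e-12)

    def test_monotone_in_dose_on_random_tallies(self, fast_model, rng):
        for _ in range(30):
            s = bma_toxicity_estimates(fast_model, random_tally(rng))
            pi = np.asarray(s.pi_hat)
            assert np.all(np.diff(pi) > 0)
            assert np.all((pi > 0) & (pi < 1))

    def test_adding_dlt_never_decreases_estimates(self, fast_model, rng):
        """More observed toxicity anywhere shifts the whole curve up; a
        clean outcome shifts it down (checked over randomized tallies)."""
        for _ in range(20):
            t = random_tally(rng, max_n=5)
            base = np.asarray(bma_toxicity_estimates(fast_model, t).pi_hat)
            dose = int(rng.integers(0, 3))
            with_dlt = np.asarray(
                bma_toxicity_estimates(fast_model, t.add(dose, True)).pi_hat
            )
            without = np.asarray(
                bma_toxicity_estimates(fast_model, t.add(dose, False)).pi_hat
            )
            assert np.all(with_dlt >= base - 1e-12)
            assert np.all(without <= base + 1e-12)

    def test_order_invariance_via_tally_sufficiency(self, model):
        a = ToxicityTally.empty(3).add(0, False).add(1, True).add(1, False)
        b = ToxicityTally.empty(3).add(1, False).add(0, False).add(1, True)
        assert bma_toxicity_estimates(model, a) == bma_toxicity_estimates(model, b)


class TestOverdoseAndTermination:
    def test_target_one_gives_zero(self, model):
        m = model.replace(target_toxicity=1.0 - 1e-9)
        # pi can never exceed a target this close to 1 with any mass
        assert overdose_probability_lowest_dose(
            m, ToxicityTally.empty(3)
        ) == pytest.approx(0.0, abs=1e-6)

    def test_prior_single_skeleton_closed_form(self, single_skeleton_model):
        # Pr(p1^exp(a) > phi) = Phi(log(log(phi)/log(p1)) / sd), frozen 0.3302119214
        got = overdose_probability_lowest_dose(
            single_skeleton_model, ToxicityTally.empty(3)
        )
        closed = norm.cdf(math.log(math.log(0.2) / math.log(0.05)) / SD)
        assert closed == pytest.approx(0.3302119214, abs=1e-9)
        assert got == pytest.approx(closed, abs=1e-6)

    def test_no_termination_at_prior(self, model):
        assert not should_terminate(model, ToxicityTally.empty(3))

    def test_termination_after_six_dlts_lowest_dose(self, model):
        t = ToxicityTally((6, 0, 0), (6, 0, 0))
        p = overdose_probability_lowest_dose(model, t)
        # cross-check by Monte-Carlo posterior sampling
        rng = np.random.default_rng(5)
        draws = rng.normal(0, SD, 400_000)
        num = 0.0
        den = 0.0
        for sk in (SK1, SK2):
            w = np.exp(log_likelihood(draws, sk, t))
            thresh = math.log(math.log(0.2) / math.log(sk.probabilities[0]))
            num += (w * (draws < thresh)).sum()
            den += w.sum()
        assert p == pytest.approx(num / den, abs=0.01)
        assert p > 0.85
        assert should_terminate(model, t)

    def test_threshold_one_never_terminates(self, model):
        m = model.replace(overdose_threshold=1.0)
        assert not should_terminate(m, ToxicityTally((6, 0, 0), (6, 0, 0)))


class TestDoseAssignment:
    def test_trial_start_is_level_one(self, model):
        d = next_dose(model, ToxicityTally.empty(3), highest_tried=None)
        assert d == DoseDecision(terminate=False, dose_level=1, dose=30.0)

    def test_no_skipping_constraint(self, model):
        # after a clean first cohort the nearest-to-target dose is level 3,
        # but assignment may climb only one level
        t = ToxicityTally((3, 0, 0), (0, 0, 0))
        s = bma_toxicity_estimates(model, t)
        assert _closest_to_target(s.pi_hat, model.target_toxicity) == 3
        assert next_dose(model, t, highest_tried=1).dose_level == 2

    def test_escalation_to_top_dose(self, model):
        t = ToxicityTally((3, 3, 0), (0, 0, 0))
        assert next_dose(model, t, highest_tried=2).dose_level == 3

    def test_exact_hit_stays(self):
        assert _closest_to_target((0.2, 0.5, 0.9), 0.2) == 1

    def test_tie_breaks_to_higher_dose(self):
        assert _closest_to_target((0.15, 0.25, 0.9), 0.2) == 2

    def test_termination_decision(self, model):
        t = ToxicityTally((6, 0, 0), (6, 0, 0))
        assert next_dose(model, t, highest_tried=1).terminate


class TestMtdSelection:
    def test_study_final_tally_selects_top_dose(self, model):
        d = select_mtd(model, ToxicityTally((3, 3, 11), (0, 0, 1)))
        assert (d.dose_level, d.dose) == (3, 150.0)

    def test_requires_patients(self, model):
        with pytest.raises(ValueError):
            select_mtd(model, ToxicityTally.empty(3))


class TestConfigDocument:
    def test_json_round_trip(self, model, tmp_path):
        path = tmp_path / "model.json"
        model.to_json(path)
        from phaseone.crm import BmaCrmModel

        again = BmaCrmModel.from_json(path)
        assert again == model

    @pytest.mark.parametrize("kwargs", [
        dict(prior_model_probs=(0.7, 0.7)),
        dict(alpha_prior_sd=0.0),
        dict(target_toxicity=1.2),
        dict(estimator="magic"),
        dict(skeletons=(Skeleton((0.1, 0.2)),)),
    ])
    def test_invalid_configs_rejected(self, model, kwargs):
        with pytest.raises(ValueError):
            model.replace(**kwargs)

    def test_invalid_skeletons_rejected(self):
        with pytest.raises(ValueError):
            Skeleton((0.2, 0.1, 0.3))
        with pytest.raises(ValueError):
            Skeleton((0.0, 0.1, 0.2))

    def test_invalid_tally_rejected(self):
        with pytest.raises(ValueError):
            ToxicityTally((1, 0, 0), (2, 0, 0))
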