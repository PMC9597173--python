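"""Stochastic maintenance-methylation simulators and readout emulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methkin import mechsim
from methkin.mechsim import (
    SimulationParams,
    init_state,
    readout_replibs,
    readout_wgbs,
    simulate_distributive,
    simulate_processive,
    simulate_replicates,
    splitting_probs,
)


class TestSplittingProbs:
    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(d_l=st.floats(0.5, 500.0), d_r=st.floats(0.5, 500.0),
           lam=st.floats(0.5, 500.0))
    def test_probabilities_sum_to_one(self, d_l, d_r, lam):
        pl, pr, pu = splitting_probs(d_l, d_r, lam)
        assert 0 <= pl <= 1 and 0 <= pr <= 1 and 0 <= pu <= 1
        assert pl + pr + pu == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_of_equidistant_targets(self):
        pl, pr, _ = splitting_probs(25.0, 25.0, 36.0)
        assert pl == pytest.approx(pr, rel=1e-12)

    def test_gamblers_ruin_limit(self):
        # lambda -> inf (no unbinding): classical split d_l/(d_l + d_r)
        pl, pr, pu = splitting_probs(20.0, 50.0, 1e9)
        assert pr == pytest.approx(20.0 / 70.0, rel=1e-6)
        assert pl == pytest.approx(50.0 / 70.0, rel=1e-6)
        assert pu == pytest.approx(0.0, abs=1e-5)

    def test_one_sided_exponential(self):
        pl, pr, pu = splitting_probs(None, 40.0, 36.0)
        assert pl == 0.0
        assert pr == pytest.approx(math.exp(-40.0 / 36.0), rel=1e-12)

    def test_no_targets_always_unbinds(self):
        assert splitting_probs(None, None, 36.0) == (0.0, 0.0, 1.0)

    def test_invalid_distances_rejected(self):
        with pytest.raises(ValueError):
            splitting_probs(0.0, 10.0, 36.0)


class TestInitState:
    def test_certain_parents(self, rng):
        assert init_state(np.ones(100), rng).all()
        assert not init_state(np.zeros(100), rng).any()

    def test_frequency_matches_landscape(self, rng):
        """Replicate-mean parental state reproduces f, by direct counting."""
        f = 0.8
        draws = np.array([init_state(np.full(1, f), rng)[0]
                          for _ in range(10_000)])
        phat = draws.mean()
        assert abs(phat - f) < 3 * math.sqrt(f * (1 - f) / 10_000)


class TestDistributive:
    def test_no_targets_no_events(self, rng):
        tau = simulate_distributive(np.arange(0, 50, 5), np.zeros(10, bool),
                                    k_f=0.7, t_end=16.0, rng=rng)
        assert np.isinf(tau).all()

    def test_times_exponentially_distributed(self, rng):
        pos = np.arange(0, 50_000, 10)
        tau = simulate_distributive(pos, np.ones(len(pos), bool),
                                    k_f=0.7, t_end=1e9, rng=rng)
        _, p = stats.kstest(tau, "expon", args=(0, 1 / 0.7))
        assert p > 0.01

    def test_truncation_at_horizon(self, rng):
        pos = np.arange(0, 10_000, 10)
        tau = simulate_distributive(pos, np.ones(len(pos), bool),
                                    k_f=0.1, t_end=2.0, rng=rng)
        finite = np.isfinite(tau)
        assert (tau[finite] <= 2.0).all()
        assert np.isinf(tau[~finite]).all() and (~finite).any()


class TestProcessive:
    def test_zero_lambda_matches_distributive_marginals(self, rng):
        pos = np.arange(0, 40_000, 8)
        par = np.ones(len(pos), bool)
        tau_p = simulate_processive(pos, par, k_f=0.7, lam=0.0, t_end=1e9,
                                    rng=rng)
        tau_d = simulate_distributive(pos, par, k_f=0.7, t_end=1e9, rng=rng)
        _, p = stats.ks_2samp(tau_p, tau_d)
        assert p > 0.01

    def test_isolated_pair_chain_probability(self):
        """First-event regime: P(pair co-methylated in one chain) = e^{-d/lam},
        counted directly over replicates."""
        d, lam, k_f, t_end, n_rep = 30, 36.0, 0.7, 0.05, 60_000
        rng = np.random.default_rng(77)
        pos = np.array([0, d])
        both = 0
        any_event = 0
        for _ in range(n_rep):
            tau = simulate_processive(pos, np.ones(2, bool), k_f, lam, t_end, rng)
            finite = np.isfinite(tau)
            if finite.any():
                any_event += 1
                if finite.all() and tau[0] == tau[1]:
                    both += 1
        p_hat = both / any_event
        p_true = math.exp(-d / lam)
        se = math.sqrt(p_true * (1 - p_true) / any_event)
        # small correction allowance: both clocks may fire separately
        assert abs(p_hat - p_true) < 4 * se + 0.01

    def test_event_conservation_and_parent_gating(self, rng):
        pos = np.cumsum(rng.integers(2, 30, 2_000))
        f = np.full(2_000, 0.6)
        params = SimulationParams("processive", k_f=0.7, lam=36.0, t_end=17.0,
                                  n_replicates=3)
        parental, tau = simulate_replicates(pos, f, params, rng)
        methylated = np.isfinite(tau)
        assert (methylated.sum(axis=1) <= parental.sum(axis=1)).all()
        # sites with unmethylated parent never gain nascent methylation
        assert not methylated[~parental].any()

    def test_chain_times_match_seeding_clock(self, rng):
        # all tau values in a chain equal the seeding clock time, so the set
        # of distinct finite times cannot exceed the number of seeds
        pos = np.arange(0, 200, 4)
        tau = simulate_processive(pos, np.ones(50, bool), k_f=0.7, lam=50.0,
                                  t_end=17.0, rng=rng)
        finite = tau[np.isfinite(tau)]
        # with lam >> spacing chains certainly fire, so times are shared
        assert 0 < len(np.unique(finite)) < len(finite)


class TestReadouts:
    def test_wgbs_requires_full_window(self, rng):
        tau = np.zeros((3, 4))
        with pytest.raises(ValueError):
            readout_wgbs(tau, rng, t_end=17.0)

    def test_wgbs_fraction_is_replicate_average(self, rng):
        # deterministic trajectories: tau=0 -> always methylated at readout,
        # inf -> never; the fraction is the replicate mean exactly
        tau = np.full((10, 6), np.inf)
        tau[:4, 0] = 0.0
        tau[:, 1] = 0.0
        frac = readout_wgbs(tau, rng, t_end=24.0)
        assert frac[0] == pytest.approx(0.4)
        assert frac[1] == pytest.approx(1.0)
        assert frac[2:].sum() == 0.0

    def test_wgbs_long_time_recapitulates_landscape(self, rng):
        """With fast kinetics the 0-24 h readout returns the input f."""
        pos = np.arange(0, 30_000, 10)
        f = np.full(len(pos), 0.8)
        params = SimulationParams("distributive", k_f=5.0, t_end=24.0,
                                  n_replicates=200)
        _, tau = simulate_replicates(pos, f, params, rng)
        frac = readout_wgbs(tau, rng, t_end=24.0)
        expected = 0.8 * (1 - (1 - np.exp(-5 * 24)) / (5 * 24))
        assert abs(frac.mean() - expected) < 0.01

    def test_replibs_all_chase16_methylated_for_early_times(self, rng):
        tau = np.full((5, 40), 0.5)
        reads = readout_replibs(tau, depth=40, rng=rng)
        late = reads[reads["t_chase_h"] == 16.0]
        assert (late["call"] == 1).all()

    def test_replibs_pooled_fraction_matches_tau_cdf(self, rng):
        """Pooled methylated fraction per chase time equals the
        replicate-averaged window probability computed from tau directly."""
        n_rep, n_sites = 8, 400
        tau = rng.exponential(1.5, size=(n_rep, n_sites))
        reads = readout_replibs(tau, depth=200, rng=rng)
        for t in (0.0, 1.0, 4.0, 16.0):
            grid = t + np.linspace(0, 1, 201)
            p_true = np.mean([(tau <= g).mean() for g in grid])
            sub = reads[reads["t_chase_h"] == t]
            se = math.sqrt(p_true * (1 - p_true) / len(sub))
            assert abs(sub["call"].mean() - p_true) <= 4 * se + 1e-12

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SimulationParams(mechanism="teleporting")
        with pytest.raises(ValueError):
            SimulationParams(k_f=-1.0)
        with pytest.raises(ValueError):
            SimulationParams.from_diffusion(D=-5.0, k_off=1.0)

    def test_from_diffusion_lambda(self):
        params = SimulationParams.from_diffusion(D=1300.0, k_off=1.0)
        assert params.lam == pytest.approx(math.sqrt(1300.0))
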