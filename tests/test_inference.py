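import itertools

import numpy as np
import pytest

from warblerdiv.blocks import BlockSpec, MutationConfig, aggregate_bsfs, configs_from_array
from warblerdiv.coalescent import ModelParams, sample_branch_lengths, simulate_block_configs
from warblerdiv.inference import (
    DEFAULT_BOUNDS,
    LikelihoodOptions,
    MutationModel,
    composite_log_likelihood,
    config_log_prob,
    fit_model,
    moment_start,
)

MUT = MutationModel()
U = MUT.u_block


def _bsfs(counts, kmax=2, spec=None):
    return aggregate_bsfs(configs_from_array(np.asarray(counts), kmax), spec or BlockSpec())


class TestConfigLogProb:
    def test_zero_count_closed_form(self):
        # single genealogy, lambda = 0.01 * 100 = 1: P(0,0,0,0) = e^-1
        L = np.array([[100.0, 0.0, 0.0, 0.0]])
        assert config_log_prob(MutationConfig(0, 0, 0, 0), L, 0.01, 2) == pytest.approx(-1.0)

    def test_one_count_closed_form(self):
        # Pois(1; 1) = e^-1 as well
        L = np.array([[100.0, 0.0, 0.0, 0.0]])
        assert config_log_prob(MutationConfig(1, 0, 0, 0), L, 0.01, 2) == pytest.approx(-1.0)

    def test_impossible_event_floored_and_flagged(self):
        L = np.array([[100.0, 0.0, 0.0, 0.0]])
        logp, flagged = config_log_prob(
            MutationConfig(0, 1, 0, 0), L, 0.01, 2, return_flag=True
        )
        assert flagged
        assert logp == pytest.approx(np.log(1.0 / 2.0))  # one genealogy -> 1/(n+1)

    def test_zero_mutation_rate_certain_empty_config(self):
        L = np.array([[50.0, 10.0, 5.0, 2.0]])
        assert config_log_prob(MutationConfig(0, 0, 0, 0), L, 0.0, 2) == pytest.approx(0.0)

    def test_capped_entry_uses_poisson_tail(self):
        lam = 0.7
        L = np.array([[lam / U, 0.0, 0.0, 0.0]])
        cfg = MutationConfig(3, 0, 0, 0, capped=(True, False, False, False))
        tail = 1 - np.exp(-lam) * (1 + lam + lam**2 / 2)
        assert config_log_prob(cfg, L, U, 2) == pytest.approx(np.log(tail))

    @pytest.mark.parametrize("seed", [3, 17])
    def test_capped_space_probabilities_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        params = ModelParams("SI", 2e5, 3e5, 9e5, 7e5)
        L = sample_branch_lengths(params, 400, rng)
        kmax = 2
        total = 0.0
        for vals in itertools.product(range(kmax + 2), repeat=4):
            cfg = MutationConfig(*vals, capped=tuple(v == kmax + 1 for v in vals))
            total += np.exp(config_log_prob(cfg, L, U, kmax, floor=False))
        assert total == pytest.approx(1.0, abs=1e-6)


class TestCompositeLikelihood:
    def test_empty_table_is_zero(self):
        assert (
            composite_log_likelihood(
                _bsfs(np.zeros((0, 4))), ModelParams("SI", 1e4, 1e4, 1e4, 1e4),
                MUT, LikelihoodOptions(200, 0),
            )
            == 0.0
        )

    def test_invariant_to_config_order(self):
        rng = np.random.default_rng(5)
        params = ModelParams("SI", 1e5, 1e5, 1e5, 2e5)
        counts = simulate_block_configs(params, U, 2000, rng)
        opts = LikelihoodOptions(500, 9)
        a = composite_log_likelihood(_bsfs(counts), params, MUT, opts)
        b = composite_log_likelihood(_bsfs(counts[::-1]), params, MUT, opts)
        assert a == pytest.approx(b, rel=1e-12)

    def test_truth_beats_doubled_split_time_usually(self):
        truth = ModelParams("SI", 2e5, 2e5, 2e5, 5e5)
        wrong = ModelParams("SI", 2e5, 2e5, 2e5, 1e6)
        wins = 0
        for trial in range(20):
            rng = np.random.default_rng(1000 + trial)
            counts = simulate_block_configs(truth, U, 2000, rng)
            bsfs = _bsfs(counts)
            opts = LikelihoodOptions(500, 2000 + trial)
            if composite_log_likelihood(bsfs, truth, MUT, opts) >= composite_log_likelihood(
                bsfs, wrong, MUT, opts
            ):
                wins += 1
        assert wins >= 19


class TestFitModel:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(31)
        truth = ModelParams("SI", 1e5, 1e5, 2e5, 3e5)
        bsfs = _bsfs(simulate_block_configs(truth, U, 3000, rng))
        opts = LikelihoodOptions(300, 77)
        a = fit_model(bsfs, "SI", MUT, opts, max_iter=60)
        b = fit_model(bsfs, "SI", MUT, opts, max_iter=60)
        assert a.params == b.params and a.cl == b.cl and a.n_iter == b.n_iter

    def test_empty_configuration_data_pushes_sizes_to_lower_bound(self):
        bsfs = _bsfs(np.zeros((500, 4), dtype=int))
        fit = fit_model(bsfs, "SI", MUT, LikelihoodOptions(200, 1), max_iter=150)
        lo = DEFAULT_BOUNDS["N_south"][0]
        # no mutations: likelihood maximized by the shortest possible trees
        assert fit.params.N_south == pytest.approx(lo, rel=0.1)
        assert fit.params.N_north == pytest.approx(lo, rel=0.1)

    def test_im_fit_on_si_data_nests_si(self):
        rng = np.random.default_rng(41)
        truth = ModelParams("SI", 2e5, 2e5, 2e5, 5e5)
        bsfs = _bsfs(simulate_block_configs(truth, U, 4000, rng))
        f_si = fit_model(bsfs, "SI", MUT, LikelihoodOptions(400, 5), max_iter=120)
        f_im = fit_model(bsfs, "IM1", MUT, LikelihoodOptions(400, 5), max_iter=120)
        # IM nests SI; allow for Monte Carlo noise between the two surfaces
        eps = 30.0
        assert f_im.cl >= f_si.cl - eps

    def test_start_outside_bounds_rejected(self):
        bsfs = _bsfs(np.zeros((10, 4), dtype=int))
        start = ModelParams("SI", 1e4, 1e4, 1e4, 1e4)
        with pytest.raises(ValueError):
            fit_model(
                bsfs, "SI", MUT, LikelihoodOptions(200, 0), start=start,
                bounds={k: (1e5, 1e6) for k in ("N_anc", "N_south", "N_north", "T")},
            )

    def test_moment_start_lands_inside_default_bounds(self):
        rng = np.random.default_rng(51)
        truth = ModelParams("SI", 2e5, 3e5, 9e5, 7e5)
        bsfs = _bsfs(simulate_block_configs(truth, U, 5000, rng))
        start = moment_start(bsfs, "SI", MUT, DEFAULT_BOUNDS)
        for name in ("N_anc", "N_south", "N_north", "T"):
            lo, hi = DEFAULT_BOUNDS[name]
            assert lo <= getattr(start, name) <= hi
        # crude moments should land within a factor ~3 of truth here
        assert 1e5 < start.N_south < 1e6
        assert 1e5 < start.T < 3e6
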