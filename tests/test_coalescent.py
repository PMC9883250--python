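"""Checks of the structured-coalescent sampler against analytic results,
an independent scalar implementation, and msprime."""

import numpy as np
import pytest

from warblerdiv.coalescent import (
    BranchLengths,
    ModelParams,
    RecombinationOptions,
    panmictic_expected_lengths,
    sample_branch_lengths,
    sample_genealogy,
    simulate_block_configs,
)


# ---------------------------------------------------------------------------
# independent scalar reference sampler (event list, pure python)
# ---------------------------------------------------------------------------

_TYPE = {
    (1, 0): 0, (0, 1): 1, (1, 1): 2, (2, 0): 3, (0, 2): 3, (2, 1): 1, (1, 2): 0,
}


def scalar_reference(params: ModelParams, rng) -> np.ndarray:
    """One genealogy via a simple per-event loop, independent of the package code."""
    lin = [((1, 0), "S"), ((1, 0), "S"), ((0, 1), "N"), ((0, 1), "N")]
    if params.T == 0:
        lin = [(c, "A") for c, _ in lin]
    sizes = {"S": params.N_south, "N": params.N_north, "A": params.N_anc}
    src = "N" if params.model == "IM1" else "S"
    dst = "S" if src == "N" else "N"
    t = 0.0
    L = np.zeros(4)
    while len(lin) > 1:
        rates = []
        for d in ("S", "N", "A"):
            k = sum(1 for _, dd in lin if dd == d)
            rates.append(("coal", d, k * (k - 1) / 2 / (2 * sizes[d])))
        if t < params.T and params.m_e > 0:
            k = sum(1 for _, dd in lin if dd == src)
            rates.append(("mig", src, params.m_e * k))
        total = sum(r for _, _, r in rates)
        dt = rng.exponential(1 / total) if total > 0 else np.inf
        if t < params.T and t + dt >= params.T:
            for comp, _ in lin:
                if comp in _TYPE:
                    L[_TYPE[comp]] += params.T - t
            lin = [(c, "A") for c, _ in lin]
            t = params.T
            continue
        for comp, _ in lin:
            if comp in _TYPE:
                L[_TYPE[comp]] += dt
        t += dt
        u = rng.random() * total
        acc = 0.0
        for kind, d, r in rates:
            acc += r
            if u < acc:
                break
        members = [i for i, (_, dd) in enumerate(lin) if dd == d]
        if kind == "coal":
            i, j = rng.choice(members, size=2, replace=False)
            (c1, _), (c2, _) = lin[int(i)], lin[int(j)]
            merged = (c1[0] + c2[0], c1[1] + c2[1])
            lin = [x for k2, x in enumerate(lin) if k2 not in (int(i), int(j))]
            lin.append((merged, d))
        else:
            i = int(rng.choice(members))
            lin[i] = (lin[i][0], dst)
    return L


class TestAnalyticOracle:
    def test_panmictic_closed_form(self):
        bl = panmictic_expected_lengths(3)
        assert (bl.hetA, bl.hetB, bl.hetAB, bl.fixed) == (8, 8, 4, 2)
        bl = panmictic_expected_lengths(0.75)
        assert (bl.hetA, bl.hetB, bl.hetAB, bl.fixed) == (2, 2, 1, 0.5)

    def test_classified_lengths_sum_to_total_tree_length(self):
        # n=4 total expected length is sum over i of 4N/i = 22N/3
        N = 1e4
        assert np.isclose(panmictic_expected_lengths(N).as_array().sum(), 22 * N / 3)

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            panmictic_expected_lengths(0)

    def test_monte_carlo_matches_panmictic_expectations(self):
        N = 1e4
        rng = np.random.default_rng(101)
        L = sample_branch_lengths(ModelParams("SI", N, N, N, 0.0), 40_000, rng)
        expect = panmictic_expected_lengths(N).as_array()
        z = (L.mean(0) - expect) / (L.std(0) / np.sqrt(len(L)))
        assert np.all(np.abs(z) < 4)


class TestStructuredModel:
    def test_matches_scalar_reference_si(self):
        params = ModelParams("SI", N_anc=1e4, N_south=2e4, N_north=3e4, T=8e4)
        rng = np.random.default_rng(7)
        ref = np.array([scalar_reference(params, rng) for _ in range(8000)])
        L = sample_branch_lengths(params, 8000, np.random.default_rng(8))
        se = np.sqrt(ref.var(0) / len(ref) + L.var(0) / len(L))
        assert np.all(np.abs(ref.mean(0) - L.mean(0)) < 4 * se)

    def test_matches_scalar_reference_im(self):
        params = ModelParams("IM1", N_anc=1e4, N_south=2e4, N_north=2e4, T=2e5, m_e=5e-6)
        rng = np.random.default_rng(9)
        ref = np.array([scalar_reference(params, rng) for _ in range(8000)])
        L = sample_branch_lengths(params, 8000, np.random.default_rng(10))
        se = np.sqrt(ref.var(0) / len(ref) + L.var(0) / len(L))
        assert np.all(np.abs(ref.mean(0) - L.mean(0)) < 4 * se)

    def test_deep_split_hetA_approaches_within_population_limit(self):
        # with T >> N the two southern singleton branches total ~ 4 N_south
        params = ModelParams("SI", N_anc=1e4, N_south=2e4, N_north=3e4, T=5e6)
        L = sample_branch_lengths(params, 20_000, np.random.default_rng(11))
        assert np.isclose(L[:, 0].mean(), 4 * params.N_south, rtol=0.05)

    def test_fixed_length_increases_with_split_time(self):
        means = []
        for T in (1e4, 1e5, 5e5, 2e6):
            params = ModelParams("SI", 1e4, 1e4, 1e4, T)
            L = sample_branch_lengths(params, 5000, np.random.default_rng(12))
            means.append(L[:, 3].mean())
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_fixed_length_slope_two_in_deep_splits(self):
        params = ModelParams("SI", 1e4, 1e4, 1e4, 4e6)
        L = sample_branch_lengths(params, 20_000, np.random.default_rng(13))
        # E[L_fixed] ~ 2T + O(N)
        assert abs(L[:, 3].mean() - 2 * params.T) < 0.05 * 2 * params.T

    def test_migration_reduces_fixed_differences(self):
        T = 1e6
        si = sample_branch_lengths(
            ModelParams("SI", 1e4, 1e4, 1e4, T), 5000, np.random.default_rng(14)
        )
        im = sample_branch_lengths(
            ModelParams("IM1", 1e4, 1e4, 1e4, T, m_e=1e-5),
            5000,
            np.random.default_rng(15),
        )
        assert im[:, 3].mean() < si[:, 3].mean()

    def test_single_genealogy_wrapper(self):
        bl = sample_genealogy(
            ModelParams("SI", 1e4, 1e4, 1e4, 1e4), np.random.default_rng(0)
        )
        assert isinstance(bl, BranchLengths)
        assert all(x >= 0 for x in bl.as_array())

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ModelParams("SI", 0, 1e4, 1e4, 1e4)
        with pytest.raises(ValueError):
            ModelParams("SI", 1e4, 1e4, 1e4, 1e4, m_e=1e-7)
        with pytest.raises(ValueError):
            ModelParams("IM1", 1e4, 1e4, 1e4, 1e4, m_e=0.0)


class TestBlockSimulation:
    def test_zero_mutation_rate_all_empty(self):
        params = ModelParams("SI", 1e4, 1e4, 1e4, 1e4)
        counts = simulate_block_configs(params, 0.0, 500, np.random.default_rng(1))
        assert counts.shape == (500, 4) and not counts.any()

    def test_same_seed_reproducible(self):
        params = ModelParams("IM2", 1e4, 1e4, 2e4, 1e5, m_e=1e-6)
        a = simulate_block_configs(params, 1e-3, 300, np.random.default_rng(21))
        b = simulate_block_configs(params, 1e-3, 300, np.random.default_rng(21))
        assert (a == b).all()

    def test_panmictic_mean_counts_match_branch_expectation(self):
        N, u = 1e4, 1e-4 * 64
        params = ModelParams("SI", N, N, N, 0.0)
        counts = simulate_block_configs(params, u, 50_000, np.random.default_rng(22))
        expect = u * panmictic_expected_lengths(N).as_array()
        se = counts.std(0) / np.sqrt(len(counts))
        assert np.all(np.abs(counts.mean(0) - expect) < 4 * se)

    def test_recombination_preserves_marginal_means(self):
        # per-site marginals are unchanged; only within-block correlation drops
        N, u = 2e4, 2e-3
        params = ModelParams("SI", N, N, N, 1e5)
        recomb = RecombinationOptions.from_cM_per_Mb(50.0)  # exaggerated rate
        a = simulate_block_configs(params, u, 20_000, np.random.default_rng(23))
        b = simulate_block_configs(
            params, u, 20_000, np.random.default_rng(24), recomb=recomb
        )
        se = np.sqrt(a.var(0) / len(a) + b.var(0) / len(b))
        assert np.all(np.abs(a.mean(0) - b.mean(0)) < 4 * se)
        # recombination shrinks the variance of per-block totals
        assert b.sum(1).var() < a.sum(1).var()


class TestMsprimeCrossCheck:
    @pytest.mark.parametrize(
        "model,m_e", [("SI", 0.0), ("IM1", 2e-6)], ids=["SI", "IM1"]
    )
    def test_config_distribution_matches_msprime(self, model, m_e):
        import msprime
        from scipy.stats import ks_2samp

        N_anc, N_s, N_n, T = 1e4, 2e4, 3e4, 1e5
        u_block = 2e-3
        n_rep = 2000

        dem = msprime.Demography()
        dem.add_population(name="south", initial_size=N_s)
        dem.add_population(name="north", initial_size=N_n)
        dem.add_population(name="anc", initial_size=N_anc)
        dem.add_population_split(time=T, derived=["south", "north"], ancestral="anc")
        if m_e > 0:
            # backwards-in-time movement of north lineages into south
            dem.set_migration_rate(source="north", dest="south", rate=m_e)

        counts = np.zeros((n_rep, 4), dtype=int)
        reps = msprime.sim_ancestry(
            samples={"south": 1, "north": 1},
            demography=dem,
            ploidy=2,
            num_replicates=n_rep,
            random_seed=42,
        )
        rng = np.random.default_rng(43)
        for r, ts in enumerate(reps):
            mts = msprime.sim_mutations(
                ts,
                rate=u_block,
                random_seed=int(rng.integers(1, 2**31)),
                discrete_genome=False,
            )
            for var in mts.variants():
                g = var.genotypes
                a, b = sorted(g[:2]), sorted(g[2:])
                hA, hB = a[0] != a[1], b[0] != b[1]
                if hA and hB:
                    counts[r, 2] += 1
                elif hA:
                    counts[r, 0] += 1
                elif hB:
                    counts[r, 1] += 1
                elif a[0] != b[0]:
                    counts[r, 3] += 1

        params = ModelParams(model, N_anc, N_s, N_n, T, m_e)
        ours = simulate_block_configs(
            params, u_block, n_rep, np.random.default_rng(44)
        )
        for col in range(4):
            stat = ks_2samp(counts[:, col], ours[:, col])
            assert stat.pvalue > 0.01, f"type {col} distribution differs"
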