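import math
from fractions import Fraction as F

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from warblerdiv.io_formats import VariantSite
from warblerdiv.sumstats import (
    SFSSpectrum,
    diversity_divergence,
    divergence_time_years,
    fst_scan,
    net_divergence,
    relative_node_depth,
    sfs_neutrality_stats,
    weir_cockerham_components,
)


def _site(pos, gts, chrom="chr1"):
    return VariantSite(chrom, pos, "A", "T", tuple(gts))


SOUTH, NORTH = [0, 1], [2, 3]


class TestDiversityDivergence:
    def test_monomorphic_data_all_zero(self):
        sites = [_site(10, [(0, 0)] * 4)]
        assert diversity_divergence(sites, SOUTH, NORTH, 100) == (0.0, 0.0, 0.0)

    def test_single_site_pair_counting(self):
        # south haplotypes {A,A,T,T}; north {A,A,A,A}; one callable site
        sites = [_site(10, [(0, 0), (1, 1), (0, 0), (0, 0)])]
        pi_s, pi_n, dxy = diversity_divergence(sites, SOUTH, NORTH, 1)
        assert pi_s == pytest.approx(4 / 6)
        assert pi_n == 0.0
        assert dxy == pytest.approx(0.5)

    def test_zero_callable_sites_rejected(self):
        with pytest.raises(ValueError):
            diversity_divergence([], SOUTH, NORTH, 0)

    def test_dxy_grows_with_split_time_in_simulation(self):
        # coalescent expectation: dxy = 2 mu (T + 2 N_anc) under SI
        from warblerdiv.coalescent import ModelParams, sample_branch_lengths

        mu = 4.6e-9
        vals = []
        for T in (2e5, 8e5):
            params = ModelParams("SI", 2e5, 2e5, 2e5, T)
            L = sample_branch_lengths(params, 20_000, np.random.default_rng(3))
            # mean difference per cross-population haplotype pair: each het
            # class separates 2 of the 4 pairs, a fixed branch all 4
            dxy = mu * (
                0.5 * (L[:, 0].mean() + L[:, 1].mean() + L[:, 2].mean())
                + L[:, 3].mean()
            )
            vals.append(dxy)
            expect = 2 * mu * (T + 2 * 2e5)
            assert dxy == pytest.approx(expect, rel=0.05)
        assert vals[0] < vals[1]


class TestNetDivergenceAndClock:
    def test_net_divergence_arithmetic(self):
        assert net_divergence(0.01, 0.004, 0.006) == pytest.approx(0.005)
        assert net_divergence(0.005, 0.005, 0.005) == pytest.approx(0.0)

    def test_da_never_exceeds_dxy_for_nonnegative_diversity(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            dxy, pi_s, pi_n = rng.random(3) * 0.02
            assert net_divergence(dxy, pi_s, pi_n) <= dxy

    def test_rnd_examples(self):
        assert relative_node_depth(0.01, 0.02, 0.02) == pytest.approx(0.5)
        assert relative_node_depth(0.03, 0.03, 0.03) == pytest.approx(1.0)

    def test_rnd_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            relative_node_depth(0.01, 0.0, 0.0)

    def test_time_conversion_examples(self):
        assert divergence_time_years(0.0) == 0.0
        assert divergence_time_years(2.7712e-3) == pytest.approx(512_000, rel=2e-4)

    def test_printed_region_times_reproduced(self):
        # net-divergence values at printed precision for the three divergent
        # regions (chromosomes 1, 3, 5) and the times they convert to
        for d_a, kyr in [(2.770824e-3, 512), (2.944000e-3, 544), (2.916941e-3, 539)]:
            assert divergence_time_years(d_a) == pytest.approx(kyr * 1000, rel=1e-4)

    @given(
        d_a=st.floats(1e-6, 1e-1),
        mu=st.floats(1e-10, 1e-7),
        gen=st.floats(0.5, 20),
    )
    @settings(max_examples=50, deadline=None)
    def test_conversion_scaling_properties(self, d_a, mu, gen):
        t = divergence_time_years(d_a, mu, gen)
        assert divergence_time_years(2 * d_a, mu, gen) == pytest.approx(2 * t, rel=1e-9)
        assert divergence_time_years(d_a, 2 * mu, gen) == pytest.approx(t / 2, rel=1e-9)
        assert divergence_time_years(d_a, mu, 2 * gen) == pytest.approx(2 * t, rel=1e-9)


def _wc_oracle(ns, ps, hs):
    """Literal transcription of the 1984 variance-component formulas, exact arithmetic."""
    r = F(len(ns))
    nbar = sum(ns, F(0)) / r
    nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
    a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


class TestFst:
    def test_fixed_difference_is_one(self):
        sites = [_site(10, [(1, 1), (1, 1), (0, 0), (0, 0)])]
        per_site, _ = fst_scan(sites, SOUTH, NORTH, maf_min=0.1)
        assert per_site[0] == pytest.approx(1.0)

    def test_identical_frequencies_near_zero(self):
        sites = [_site(10, [(0, 1), (0, 1), (0, 1), (0, 1)])]
        per_site, _ = fst_scan(sites, SOUTH, NORTH, maf_min=0.1)
        assert per_site[0] < 0.05

    def test_toy_table_matches_exact_oracle(self):
        # south {0/0, 0/1, 0/1, 1/1}, north {0/0, 0/0, 0/1, 0/0}
        gts_s = [(0, 0), (0, 1), (0, 1), (1, 1)]
        gts_n = [(0, 0), (0, 0), (0, 1), (0, 0)]
        sites = [_site(10, gts_s + gts_n)]
        per_site, _ = fst_scan(sites, [0, 1, 2, 3], [4, 5, 6, 7], maf_min=0.1)
        a, b, c = _wc_oracle(
            [F(4), F(4)], [F(1, 2), F(1, 8)], [F(1, 2), F(1, 4)]
        )
        expect = float(a / (a + b + c))
        assert expect == pytest.approx(1 / 6)
        assert abs(per_site[0] - expect) < 1e-10

    def test_component_formula_matches_oracle_on_random_tables(self, rng):
        for _ in range(50):
            ns = rng.integers(2, 10, size=2)
            alt = [rng.integers(0, 2 * n + 1) for n in ns]
            het = [rng.integers(0, min(a, 2 * n - a) + 1) for a, n in zip(alt, ns)]
            ps = [F(int(a), int(2 * n)) for a, n in zip(alt, ns)]
            hs = [F(int(h), int(n)) for h, n in zip(het, ns)]
            a, b, c = weir_cockerham_components(
                np.array(ns, dtype=float),
                np.array([float(p) for p in ps]),
                np.array([float(h) for h in hs]),
            )
            ea, eb, ec = _wc_oracle([F(int(n)) for n in ns], ps, hs)
            assert a == pytest.approx(float(ea), abs=1e-10)
            assert b == pytest.approx(float(eb), abs=1e-10)
            assert c == pytest.approx(float(ec), abs=1e-10)

    def test_maf_filter_and_empty_windows(self):
        # singleton variant: pooled MAF 1/8 < 0.15 -> filtered, window empty
        sites = [_site(10, [(0, 1), (0, 0), (0, 0), (0, 0)])]
        per_site, windows = fst_scan(sites, SOUTH, NORTH, maf_min=0.15, window=1000)
        assert per_site == [None]
        assert windows == []

    def test_windowed_value_is_ratio_of_sums_and_bounded(self, rng):
        sites = []
        for pos in range(1, 120):
            gts = [tuple(sorted(rng.integers(0, 2, size=2))) for _ in range(4)]
            sites.append(_site(pos, gts))
        per_site, windows = fst_scan(sites, SOUTH, NORTH, maf_min=0.1, window=50)
        for w in windows:
            if w.value is not None:
                assert w.value <= 1.0


def _neutrality_oracle(n, counts):
    """Exact-fraction evaluation of theta_pi, theta_W, theta_H, D, H."""
    S_i = [F(c) for c in counts]
    S = sum(S_i)
    denom = F(n * (n - 1))
    theta_pi = sum(2 * s * i * (n - i) for s, i in zip(S_i, range(1, n))) / denom
    theta_H = sum(2 * s * i * i for s, i in zip(S_i, range(1, n))) / denom
    H = theta_pi - theta_H
    if S == 0:
        return None, float(H)
    a1 = sum(F(1, i) for i in range(1, n))
    a2 = sum(F(1, i * i) for i in range(1, n))
    b1 = F(n + 1, 3 * (n - 1))
    b2 = F(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - F(n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1)
    D = float(theta_pi - S / a1) / math.sqrt(float(var))
    return D, float(H)


class TestNeutralityStats:
    def test_singleton_excess_gives_negative_d(self):
        d, _ = sfs_neutrality_stats(SFSSpectrum(n=10, counts=(30,) + (0,) * 8))
        assert d < 0

    def test_high_frequency_derived_gives_negative_h(self):
        _, h = sfs_neutrality_stats(SFSSpectrum(n=10, counts=(0,) * 8 + (20,)))
        assert h < 0

    def test_hand_worked_small_spectrum(self):
        d, h = sfs_neutrality_stats(SFSSpectrum(n=4, counts=(3, 0, 0)))
        assert h == pytest.approx(1.0, abs=1e-10)
        assert d == pytest.approx(-0.7544510776527716, abs=1e-10)

    @pytest.mark.parametrize(
        "n,counts",
        [(4, (3, 0, 0)), (4, (1, 2, 5)), (6, (2, 0, 1, 0, 4)), (8, (0,) * 7)],
    )
    def test_matches_exact_oracle(self, n, counts):
        d, h = sfs_neutrality_stats(SFSSpectrum(n=n, counts=counts))
        ed, eh = _neutrality_oracle(n, counts)
        assert h == pytest.approx(eh, abs=1e-10)
        if ed is None:
            assert d is None
        else:
            assert d == pytest.approx(ed, abs=1e-10)

    def test_no_segregating_sites_d_undefined_not_zero(self):
        d, h = sfs_neutrality_stats(SFSSpectrum(n=6, counts=(0,) * 5))
        assert d is None
        assert h == 0.0
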