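"""Structured-coalescent sampling for two diploids from a two-population split.

The sampler follows four lineages (two haplotypes sampled in the southern
population, two in the northern) backwards in time under three demographic
models:

``SI``
    Strict isolation: the populations split ``T`` generations ago from an
    ancestral population of diploid size ``N_anc`` and exchange no migrants.
``IM1``
    As SI, plus constant migration from south to north (forwards in time) at
    per-lineage per-generation probability ``m_e``.  Backwards in time,
    lineages currently in the north jump to the south at rate ``m_e``.
``IM2``
    Mirror image: forwards migration north to south; backwards, southern
    lineages jump north.

Each genealogy is reduced to the total branch length whose mutations would
produce each of the four blockwise mutation types for a pair of diploids
(one per population):

* ``hetA``  — heterozygous in the southern sample only,
* ``hetB``  — heterozygous in the northern sample only,
* ``hetAB`` — heterozygous in both,
* ``fixed`` — homozygous difference between the samples.

A branch is classified by its descendant haplotypes: one southern haplotype
(or one southern plus both northern) yields ``hetA``; the mirror yields
``hetB``; one haplotype from each population yields ``hetAB``; both
haplotypes of either sample yield ``fixed``.  Mutations on a branch ancestral
to everything are invisible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelParams",
    "BranchLengths",
    "RecombinationOptions",
    "MODELS",
    "sample_branch_lengths",
    "sample_genealogy",
    "panmictic_expected_lengths",
    "simulate_block_configs",
]

MODELS = ("SI", "IM1", "IM2")

# Descendant compositions (n_south, n_north) a lineage can carry, and the
# mutation type each maps to.  Index 7 is the full set (the MRCA) and never
# accrues classified length because sampling stops at a single lineage.
_COMPS = [(1, 0), (0, 1), (1, 1), (2, 0), (0, 2), (2, 1), (1, 2), (2, 2)]
_COMP_INDEX = {c: i for i, c in enumerate(_COMPS)}
# type codes: 0=hetA 1=hetB 2=hetAB 3=fixed 4=none
_TYPE_OF_COMP = np.array([0, 1, 2, 3, 3, 1, 0, 4], dtype=np.int64)

_MERGE = np.full((8, 8), -1, dtype=np.int64)
for _i, (_a, _b) in enumerate(_COMPS):
    for _j, (_c, _d) in enumerate(_COMPS):
        _s = (_a + _c, _b + _d)
        if _s in _COMP_INDEX:
            _MERGE[_i, _j] = _COMP_INDEX[_s]

_SOUTH, _NORTH, _ANC = 0, 1, 2


@dataclass(frozen=True)
class ModelParams:
    """Demographic parameter point.

    Sizes are diploid effective sizes; ``T`` is the split time in
    generations; ``m_e`` is the per-lineage per-generation migration
    probability (zero and only zero for SI).
    """

    model: str
    N_anc: float
    N_south: float
    N_north: float
    T: float
    m_e: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        for name in ("N_anc", "N_south", "N_north"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if not np.isfinite(self.T) or self.T < 0:
            raise ValueError(f"T must be non-negative and finite, got {self.T}")
        if not np.isfinite(self.m_e) or self.m_e < 0:
            raise ValueError(f"m_e must be non-negative and finite, got {self.m_e}")
        if (self.model == "SI") != (self.m_e == 0.0):
            raise ValueError("m_e must be 0 exactly for SI and positive for IM models")


@dataclass(frozen=True)
class BranchLengths:
    """Per-mutation-type total branch length of one genealogy, in generations."""

    hetA: float
    hetB: float
    hetAB: float
    fixed: float

    def as_array(self) -> np.ndarray:
        return np.array([self.hetA, self.hetB, self.hetAB, self.fixed])


@dataclass(frozen=True)
class RecombinationOptions:
    """Intra-block recombination settings for block simulation.

    ``rate_per_bp`` is the per-generation crossover probability per bp;
    a map distance of 1 cM/Mb corresponds to 1e-8.
    """

    enabled: bool = False
    rate_per_bp: float = 0.0
    block_bp: int = 128

    def __post_init__(self) -> None:
        if self.rate_per_bp < 0 or not np.isfinite(self.rate_per_bp):
            raise ValueError("rate_per_bp must be non-negative and finite")
        if self.block_bp < 1:
            raise ValueError("block_bp must be >= 1")

    @classmethod
    def from_cM_per_Mb(cls, rate_cM_Mb: float, block_bp: int = 128) -> "RecombinationOptions":
        return cls(enabled=rate_cM_Mb > 0, rate_per_bp=rate_cM_Mb * 1e-8, block_bp=block_bp)


def panmictic_expected_lengths(N: float) -> BranchLengths:
    """Closed-form expected per-type branch lengths for a panmictic population.

    For four exchangeable lineages in a diploid population of size ``N``, the
    expected total length of branches with ``i`` descendants is ``4N/i``.
    Distributing each class uniformly over the labelled subsets gives
    ``(8N/3, 8N/3, 4N/3, 2N/3)`` for (hetA, hetB, hetAB, fixed).
    """
    if not np.isfinite(N) or N <= 0:
        raise ValueError(f"N must be positive, got {N}")
    return BranchLengths(8 * N / 3, 8 * N / 3, 4 * N / 3, 2 * N / 3)


def sample_branch_lengths(
    params: ModelParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``n`` genealogies and return an ``(n, 4)`` array of branch lengths.

    Columns are (hetA, hetB, hetAB, fixed) in generations.  The simulation is
    event-driven and vectorized across replicates: within each deme a pair
    coalesces at rate ``k(k-1)/2 / (2N)`` per generation, migrating lineages
    jump at rate ``m_e`` each, and at time ``T`` every remaining lineage moves
    to the ancestral deme.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    # lineage slots: S1, S2, N1, N2
    comp = np.tile(np.array([0, 0, 1, 1], dtype=np.int64), (n, 1))
    start_deme = _ANC if params.T == 0 else None
    deme = np.tile(
        np.array(
            [_SOUTH, _SOUTH, _NORTH, _NORTH]
            if start_deme is None
            else [_ANC] * 4,
            dtype=np.int64,
        ),
        (n, 1),
    )
    alive = np.ones((n, 4), dtype=bool)
    t = np.zeros(n)
    # 5 columns so that 'none' lengths have somewhere to go; dropped on return
    lengths = np.zeros((n, 5))

    T, m_e = params.T, params.m_e
    inv2 = {
        _SOUTH: 1.0 / (2.0 * params.N_south),
        _NORTH: 1.0 / (2.0 * params.N_north),
        _ANC: 1.0 / (2.0 * params.N_anc),
    }
    mig_src = _NORTH if params.model == "IM1" else _SOUTH  # backwards-in-time source

    idx = np.arange(n)
    active = idx[alive.sum(axis=1) > 1]
    while active.size:
        a = active
        m = a.size
        dm, al = deme[a], alive[a]
        ks = ((dm == _SOUTH) & al).sum(axis=1)
        kn = ((dm == _NORTH) & al).sum(axis=1)
        ka = ((dm == _ANC) & al).sum(axis=1)
        rc_s = ks * (ks - 1) / 2.0 * inv2[_SOUTH]
        rc_n = kn * (kn - 1) / 2.0 * inv2[_NORTH]
        rc_a = ka * (ka - 1) / 2.0 * inv2[_ANC]
        rm = m_e * (kn if mig_src == _NORTH else ks)
        total = rc_s + rc_n + rc_a + rm

        e = rng.exponential(size=m)
        with np.errstate(divide="ignore"):
            dt = np.where(total > 0, e / np.maximum(total, 1e-300), np.inf)
        pre_split = t[a] < T
        hit_T = pre_split & (t[a] + dt >= T)
        dt_eff = np.where(hit_T, T - t[a], dt)

        for slot in range(4):
            sl = al[:, slot]
            lengths[a[sl], _TYPE_OF_COMP[comp[a[sl], slot]]] += dt_eff[sl]
        t[a] = t[a] + dt_eff

        if hit_T.any():
            deme[a[hit_T]] = _ANC

        ev = ~hit_T
        if ev.any():
            av = a[ev]
            u = rng.random(ev.sum()) * total[ev]
            cs = u < rc_s[ev]
            cn = ~cs & (u < (rc_s + rc_n)[ev])
            ca = ~cs & ~cn & (u < (rc_s + rc_n + rc_a)[ev])
            mg = ~cs & ~cn & ~ca

            keys = rng.random((av.size, 4))
            # coalescence: merge the top-2 random keys among eligible slots
            for sel, d in ((cs, _SOUTH), (cn, _NORTH), (ca, _ANC)):
                if not sel.any():
                    continue
                r = av[sel]
                kk = keys[sel].copy()
                kk[~(alive[r] & (deme[r] == d))] = -1.0
                order = np.argsort(-kk, axis=1)
                i1, i2 = order[:, 0], order[:, 1]
                rows = np.arange(r.size)
                comp[r, i1] = _MERGE[comp[r, i1], comp[r, i2]]
                alive[r, i2] = False
            if mg.any():
                r = av[mg]
                kk = keys[mg].copy()
                kk[~(alive[r] & (deme[r] == mig_src))] = -1.0
                i1 = np.argmax(kk, axis=1)
                deme[r, i1] = _NORTH if mig_src == _SOUTH else _SOUTH

        active = a[alive[a].sum(axis=1) > 1]

    return lengths[:, :4]


def sample_genealogy(params: ModelParams, rng: np.random.Generator) -> BranchLengths:
    """Draw a single genealogy and return its per-type branch lengths."""
    L = sample_branch_lengths(params, 1, rng)[0]
    return BranchLengths(*L)


def simulate_block_configs(
    params: ModelParams,
    u_block: float,
    n_blocks: int,
    rng: np.random.Generator,
    recomb: RecombinationOptions | None = None,
    block_span: int = 64,
) -> np.ndarray:
    """Simulate per-block mutation-type counts under a demographic model.

    Returns an ``(n_blocks, 4)`` integer array of uncapped counts
    (hetA, hetB, hetAB, fixed).  ``u_block`` is the expected number of
    mutations per block per generation of branch length (mutation rate per
    site times the number of callable sites per block).

    Without recombination each block carries a single genealogy and the
    counts are Poisson with mean ``u_block * L_type``.  With recombination a
    sequential walk along the block's ``block_span`` callable sites is used:
    between adjacent sites the genealogy is renewed with a fresh independent
    draw with probability ``1 - exp(-r * d * E[L_total])``, where ``d`` is
    the mean physical spacing and ``E[L_total]`` the expected total tree
    length (estimated from the initial genealogy sample).  Renewing at a
    constant rate keeps the per-site marginal distribution exactly the
    single-site coalescent (a length-dependent redraw would cull long trees)
    while reproducing the decorrelation that intra-block recombination
    causes; the Poisson mean sums the per-site branch lengths.
    """
    if u_block < 0:
        raise ValueError("u_block must be >= 0")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if recomb is None or not recomb.enabled or recomb.rate_per_bp == 0.0:
        L = sample_branch_lengths(params, n_blocks, rng)
        return rng.poisson(u_block * L).astype(np.int64)

    u_site = u_block / block_span
    d_bp = recomb.block_bp / block_span
    L = sample_branch_lengths(params, n_blocks, rng)
    mean_total = float(L.sum(axis=1).mean())
    p_rec = -np.expm1(-recomb.rate_per_bp * d_bp * mean_total)
    mean = u_site * L.copy()
    for _ in range(block_span - 1):
        hit = rng.random(n_blocks) < p_rec
        k = int(hit.sum())
        if k:
            L[hit] = sample_branch_lengths(params, k, rng)
        mean += u_site * L
    return rng.poisson(mean).astype(np.int64)
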