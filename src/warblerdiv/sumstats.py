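"""Diversity and divergence summary statistics.

Implements the statistics used alongside the model-based divergence
estimates: within-population nucleotide diversity (pi), between-population
divergence (d_xy), net divergence d_a = d_xy - (pi_N + pi_S)/2 and its
clock conversion to years, relative node depth (RND) against an outgroup,
per-site and windowed Weir & Cockerham F_ST, Tajima's D and Fay & Wu's H
from the derived-allele frequency spectrum.

All estimators work from unphased diploid genotypes; haplotype allele counts
per site are sufficient for every quantity here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import VariantSite

__all__ = [
    "DivergenceStats",
    "WindowStat",
    "SFSSpectrum",
    "diversity_divergence",
    "net_divergence",
    "relative_node_depth",
    "divergence_time_years",
    "outgroup_divergence",
    "distance_to_outgroup_extra",
    "weir_cockerham_components",
    "fst_scan",
    "sfs_neutrality_stats",
    "genotype_matrix",
]


@dataclass(frozen=True)
class DivergenceStats:
    pi_south: float
    pi_north: float
    dxy: float
    d_a: float
    rnd: float | None
    t_years: float

    def to_dict(self) -> dict:
        return {
            "pi_south": self.pi_south,
            "pi_north": self.pi_north,
            "dxy": self.dxy,
            "d_a": self.d_a,
            "rnd": self.rnd,
            "t_years": self.t_years,
        }


@dataclass(frozen=True)
class WindowStat:
    chrom: str
    start: int  # 0-based half-open
    end: int
    statistic: str
    value: float | None  # None when no usable sites fall in the window
    n_sites: int


@dataclass(frozen=True)
class SFSSpectrum:
    """Unfolded (derived-allele) site frequency spectrum.

    ``counts[i]`` is the number of sites with derived-allele count ``i + 1``
    (frequencies 1 .. n-1); ``n`` is the haploid sample size.
    """

    n: int
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2 haplotypes")
        if len(self.counts) != self.n - 1:
            raise ValueError("counts must have length n - 1")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")

    @property
    def S(self) -> int:
        return int(sum(self.counts))


def genotype_matrix(
    sites: list[VariantSite], sample_idx: list[int]
) -> np.ndarray:
    """Alt-allele dosage matrix (n_sites, n_samples); -1 marks missing."""
    g = np.full((len(sites), len(sample_idx)), -1, dtype=np.int8)
    for i, site in enumerate(sites):
        for j, k in enumerate(sample_idx):
            gt = site.genotypes[k]
            if gt is not None:
                g[i, j] = gt[0] + gt[1]
    return g


def _allele_counts(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (alt haplotype count, total haplotype count) ignoring missing."""
    called = g >= 0
    n = 2 * called.sum(axis=1)
    a = np.where(called, g, 0).sum(axis=1)
    return a.astype(np.int64), n.astype(np.int64)


def diversity_divergence(
    sites: list[VariantSite],
    south_idx: list[int],
    north_idx: list[int],
    n_callable: int,
) -> tuple[float, float, float]:
    """Per-site pi within each population and d_xy between them.

    pi is the mean pairwise haplotype difference within a population and
    d_xy the mean difference between one haplotype from each population,
    both divided by the number of callable sites ``n_callable`` (invariant
    callable sites contribute zero differences).
    """
    if n_callable <= 0:
        raise ValueError("n_callable must be > 0")
    gs = genotype_matrix(sites, south_idx)
    gn = genotype_matrix(sites, north_idx)
    a_s, m_s = _allele_counts(gs)
    a_n, m_n = _allele_counts(gn)

    def pi_sum(a, m):
        ok = m >= 2
        a, m = a[ok].astype(float), m[ok].astype(float)
        return float((2.0 * a * (m - a) / (m * (m - 1.0))).sum())

    ok = (m_s >= 1) & (m_n >= 1)
    af_s = np.divide(a_s, m_s, out=np.zeros(len(a_s)), where=m_s > 0)
    af_n = np.divide(a_n, m_n, out=np.zeros(len(a_n)), where=m_n > 0)
    dxy_sum = float(
        (af_s[ok] * (1 - af_n[ok]) + (1 - af_s[ok]) * af_n[ok]).sum()
    )
    return (
        pi_sum(a_s, m_s) / n_callable,
        pi_sum(a_n, m_n) / n_callable,
        dxy_sum / n_callable,
    )


def net_divergence(dxy: float, pi_south: float, pi_north: float) -> float:
    """d_a = d_xy - (pi_north + pi_south) / 2."""
    return dxy - (pi_north + pi_south) / 2.0


def relative_node_depth(dxy: float, d_out_south: float, d_out_north: float) -> float:
    """RND: between-population divergence over the mean outgroup divergence."""
    denom = (d_out_south + d_out_north) / 2.0
    if denom <= 0:
        raise ValueError("outgroup divergences must be positive")
    return dxy / denom


def divergence_time_years(
    d_a: float, mu: float = 4.6e-9, gen_years: float = 1.7
) -> float:
    """Convert net divergence to years: T = d_a / (2 mu) generations.

    Under a strict clock with constant ancestral diversity, d_a accumulates
    at 2 mu per generation of separation.
    """
    if d_a < 0:
        raise ValueError("d_a must be >= 0")
    return d_a / (2.0 * mu) * gen_years


def outgroup_divergence(
    sites: list[VariantSite],
    pop_idx: list[int],
    outgroup_allele: dict[tuple[str, int], str],
    n_callable: int,
    extra_fixed: int = 0,
) -> float:
    """Mean per-site difference between a population's haplotypes and the outgroup.

    ``outgroup_allele`` maps (chrom, pos) to 'ref' or 'alt'; sites absent
    from the map are skipped.  ``extra_fixed`` adds positions where the
    outgroup differs from the reference but the in-group is invariant (such
    sites carry one full difference per haplotype and are not in the VCF).
    """
    if n_callable <= 0:
        raise ValueError("n_callable must be > 0")
    g = genotype_matrix(sites, pop_idx)
    a, m = _allele_counts(g)
    total = float(extra_fixed)
    for i, site in enumerate(sites):
        anc = outgroup_allele.get((site.chrom, site.pos))
        if anc is None or m[i] == 0:
            continue
        af = a[i] / m[i]
        total += (1 - af) if anc == "alt" else af
    return total / n_callable


def distance_to_outgroup_extra(
    outgroup_table: dict,
    vcf_positions: set[tuple[str, int]],
    min_cov: float,
) -> float:
    """Outgroup-only divergence from pileup rows absent from the VCF.

    A table row at a position with no variant record means the outgroup
    differs from the reference while the in-group is invariant: a single
    observed allele contributes one difference per in-group haplotype, two
    observed alleles (outgroup heterozygous) contribute half.  Rows below
    the coverage threshold are skipped, mirroring the polarization rule.
    """
    total = 0.0
    for key, obs in outgroup_table.items():
        if key in vcf_positions or obs.coverage < min_cov:
            continue
        k = len(obs.alleles)
        if k == 1:
            total += 1.0
        elif k == 2:
            total += 0.5
    return total


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------


def weir_cockerham_components(
    n_i: np.ndarray, p_i: np.ndarray, h_i: np.ndarray
) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) variance components (a, b, c) for one site.

    ``n_i`` are per-population genotyped sample sizes (individuals), ``p_i``
    alternate-allele frequencies and ``h_i`` observed heterozygote
    proportions.  The per-site estimator is a / (a + b + c); a windowed
    "weighted" estimator is the ratio of the summed components.
    """
    n_i = np.asarray(n_i, dtype=float)
    p_i = np.asarray(p_i, dtype=float)
    h_i = np.asarray(h_i, dtype=float)
    r = len(n_i)
    if r < 2 or (n_i <= 0).any():
        raise ValueError("need >= 2 populations with samples")
    n_bar = n_i.mean()
    n_c = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1)
    p_bar = (n_i * p_i).sum() / (r * n_bar)
    s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum() / (r * n_bar)
    if n_bar <= 1:
        raise ValueError("need more than one individual per population on average")
    a = (n_bar / n_c) * (
        s2
        - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - (r - 1) / r * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2.0
    return float(a), float(b), float(c)


def fst_scan(
    sites: list[VariantSite],
    south_idx: list[int],
    north_idx: list[int],
    maf_min: float = 0.1,
    window: int = 10_000,
) -> tuple[list[float | None], list[WindowStat]]:
    """Per-site Weir & Cockerham F_ST and windowed ratio-of-sums values.

    Sites failing the pooled minor-allele-frequency filter (or monomorphic
    across both populations) get ``None`` per site and are excluded from
    windows.  Windows are non-overlapping ``window``-bp tiles per
    chromosome; a window with no usable site has value ``None``, not 0.
    Per-site values may be negative and are not clipped.
    """
    per_site: list[float | None] = []
    comp: list[tuple[str, int, float, float] | None] = []
    for site in sites:
        parts = []
        usable = True
        alt_total = n_total = 0
        for idx in (south_idx, north_idx):
            gts = [site.genotypes[k] for k in idx if site.genotypes[k] is not None]
            n = len(gts)
            if n < 2:
                usable = False
                break
            alt = sum(g[0] + g[1] for g in gts)
            het = sum(1 for g in gts if g[0] != g[1])
            parts.append((n, alt / (2 * n), het / n))
            alt_total += alt
            n_total += 2 * n
        if not usable:
            per_site.append(None)
            comp.append(None)
            continue
        af = alt_total / n_total
        maf = min(af, 1 - af)
        if maf < maf_min or af in (0.0, 1.0):
            per_site.append(None)
            comp.append(None)
            continue
        n_i, p_i, h_i = (np.array(x) for x in zip(*parts))
        a, b, c = weir_cockerham_components(n_i, p_i, h_i)
        denom = a + b + c
        per_site.append(a / denom if denom != 0 else None)
        comp.append((site.chrom, site.pos0, a, denom))

    # windowed ratio of summed components
    wins: dict[tuple[str, int], list[float]] = {}
    for entry in comp:
        if entry is None:
            continue
        chrom, pos0, a, denom = entry
        key = (chrom, pos0 // window)
        acc = wins.setdefault(key, [0.0, 0.0, 0])
        acc[0] += a
        acc[1] += denom
        acc[2] += 1
    window_stats = [
        WindowStat(
            chrom=chrom,
            start=w * window,
            end=(w + 1) * window,
            statistic="fst_weighted",
            value=(acc[0] / acc[1]) if acc[1] != 0 else None,
            n_sites=int(acc[2]),
        )
        for (chrom, w), acc in sorted(wins.items())
    ]
    return per_site, window_stats


# ---------------------------------------------------------------------------
# SFS-based neutrality statistics
# ---------------------------------------------------------------------------


def sfs_neutrality_stats(spectrum: SFSSpectrum) -> tuple[float | None, float]:
    """Tajima's D and (unnormalized) Fay & Wu's H from an unfolded spectrum.

    D is the difference theta_pi - theta_W normalized by its standard
    deviation estimate; it is ``None`` (undefined) when there are no
    segregating sites.  H = theta_pi - theta_H with
    theta_H = sum_i 2 S_i i^2 / (n (n-1)).
    """
    n = spectrum.n
    S = spectrum.S
    i = np.arange(1, n)
    Si = np.array(spectrum.counts, dtype=float)
    denom = n * (n - 1.0)
    theta_pi = float((2.0 * Si * i * (n - i)).sum() / denom)
    theta_H = float((2.0 * Si * i * i).sum() / denom)
    fay_wu_h = theta_pi - theta_H

    if S == 0:
        return None, fay_wu_h
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    theta_w = S / a1
    var = e1 * S + e2 * S * (S - 1.0)
    if var <= 0:
        return None, fay_wu_h
    tajimas_d = (theta_pi - theta_w) / np.sqrt(var)
    return float(tajimas_d), fay_wu_h
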