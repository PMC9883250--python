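"""Synthetic site-level datasets with known demographic truth.

The generator emulates the inputs of the divergence analysis: a VCF of
biallelic SNPs for a handful of diploids from a southern and a northern
population, per-sample depth tracks (so the callable-mask rules have
something to bite on), an exclusion BED standing in for genic/repeat
annotation, and an outgroup pileup table for polarization and RND — all
simulated under an explicit two-population split model so every downstream
estimate can be compared with the truth that generated it.

The region is tiled into non-recombining segments of at most one block span
(128 bp by default); each segment gets an independent genealogy for
``2 * n_diploids`` in-group haplotypes plus two outgroup haplotypes that
join the ancestral population at a deeper split.  Mutations follow an
infinite-sites scheme: position collisions are re-drawn, except a
configurable fraction kept as multiallelic records to exercise the
biallelic filter.

Default demography: strict isolation with
``N_anc = N_south = N_north = 2e5`` and ``T = 7e5`` generations.  Equal
sizes keep the net-divergence clock exact (``E[d_a] = 2 mu T`` requires
``2 N_anc = N_south + N_north``), which makes the manifest's expectation
usable as an oracle; the asymmetric-size scenarios of interest are passed
explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import ModelParams
from .io_formats import OutgroupObservation, write_bed, write_outgroup_table

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_dataset"]

_BASES = ("A", "C", "G", "T")


def _default_params() -> ModelParams:
    return ModelParams("SI", N_anc=2e5, N_south=2e5, N_north=2e5, T=7e5)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; ``params`` is the demographic truth."""

    params: ModelParams = field(default_factory=_default_params)
    region_length: int = 500_000
    mu: float = 4.6e-9
    n_diploids: int = 2  # per in-group population
    outgroup_split: float | None = None  # generations; default 5 * T
    outgroup_Ne: float | None = None  # default N_anc
    coverage_mean: float = 30.0
    coverage_cv: float = 0.3  # window-level coefficient of variation
    outgroup_coverage_mean: float = 30.0
    exclusion_density: float = 0.05  # fraction of region covered by exclusion BED
    multihit_keep: float = 0.05  # fraction of position collisions kept multiallelic
    segment_bp: int = 128
    chrom: str = "chr_sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_length < 10 * self.segment_bp:
            raise ValueError("region_length must be >= 10 * segment_bp")
        if self.mu < 0 or self.coverage_mean < 0 or self.exclusion_density < 0:
            raise ValueError("rates must be non-negative")
        if self.n_diploids < 1:
            raise ValueError("need at least one diploid per population")
        t_out = self.outgroup_split if self.outgroup_split is not None else 5 * self.params.T
        if t_out < self.params.T:
            raise ValueError("outgroup split must not precede the in-group split")

    @property
    def t_outgroup(self) -> float:
        return self.outgroup_split if self.outgroup_split is not None else 5 * self.params.T

    @property
    def N_outgroup(self) -> float:
        return self.outgroup_Ne if self.outgroup_Ne is not None else self.params.N_anc

    def sample_names(self) -> tuple[list[str], list[str], str]:
        south = [f"S{i+1}" for i in range(self.n_diploids)]
        north = [f"N{i+1}" for i in range(self.n_diploids)]
        return south, north, "OUT"


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    vcf_path: str
    depths_path: str
    exclude_bed_path: str
    outgroup_path: str
    manifest_path: str
    manifest: dict
    n_records: int
    n_multiallelic: int


# ---------------------------------------------------------------------------
# segment genealogy: scalar structured coalescent with an outgroup deme
# ---------------------------------------------------------------------------

_S, _N, _ANC, _OUT = 0, 1, 2, 3


def _simulate_segment_branches(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> list[tuple[frozenset, float]]:
    """One genealogy for all haplotypes; returns (descendant set, length) per branch.

    Haplotype ids: 0..2k-1 southern, 2k..4k-1 northern (k = n_diploids per
    population), then two outgroup haplotypes.
    """
    p = cfg.params
    k = cfg.n_diploids
    n_in = 4 * k
    T, T_out = p.T, cfg.t_outgroup
    sizes = {_S: p.N_south, _N: p.N_north, _ANC: p.N_anc, _OUT: cfg.N_outgroup}
    mig_src = {_N: _S} if p.model == "IM1" else {_S: _N} if p.model == "IM2" else {}

    lin: list[list] = []  # [descendant frozenset, deme, birth_time]
    for h in range(2 * k):
        lin.append([frozenset([h]), _S, 0.0])
    for h in range(2 * k, 4 * k):
        lin.append([frozenset([h]), _N, 0.0])
    for h in range(n_in, n_in + 2):
        lin.append([frozenset([h]), _OUT, 0.0])

    branches: list[tuple[frozenset, float]] = []
    t = 0.0
    while len(lin) > 1:
        by_deme: dict[int, list[int]] = {}
        for i, (_, d, _b) in enumerate(lin):
            by_deme.setdefault(d, []).append(i)
        rates: list[tuple[float, str, int]] = []
        for d, members in by_deme.items():
            m = len(members)
            if m >= 2:
                rates.append((m * (m - 1) / 2.0 / (2.0 * sizes[d]), "coal", d))
        if t < T and p.m_e > 0:
            for src in mig_src:
                m = len(by_deme.get(src, []))
                if m:
                    rates.append((p.m_e * m, "mig", src))
        total = sum(r for r, _, _ in rates)
        dt = rng.exponential(1.0 / total) if total > 0 else np.inf

        next_epoch = min((x for x in (T, T_out) if x > t), default=np.inf)
        if t + dt >= next_epoch:
            t = next_epoch
            if t == T:
                for entry in lin:
                    if entry[1] in (_S, _N):
                        entry[1] = _ANC
            if t == T_out:
                for entry in lin:
                    if entry[1] == _OUT:
                        entry[1] = _ANC
            continue
        t += dt
        u = rng.random() * total
        acc = 0.0
        for r, kind, d in rates:
            acc += r
            if u < acc:
                break
        if kind == "coal":
            i, j = rng.choice(by_deme[d], size=2, replace=False)
            i, j = int(i), int(j)
            a, b = lin[i], lin[j]
            branches.append((a[0], t - a[2]))
            branches.append((b[0], t - b[2]))
            merged = [a[0] | b[0], d, t]
            lin = [x for idx, x in enumerate(lin) if idx not in (i, j)]
            lin.append(merged)
        else:
            i = int(rng.choice(by_deme[d]))
            lin[i][1] = mig_src[d]
    return branches


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


def _depth_track(
    length: int, mean: float, cv: float, rng: np.random.Generator, window: int = 1000
) -> np.ndarray:
    """Overdispersed depth: gamma window-level means, Poisson position jitter."""
    n_win = (length + window - 1) // window
    if cv > 0:
        shape = 1.0 / (cv * cv)
        win_means = rng.gamma(shape, mean / shape, size=n_win)
    else:
        win_means = np.full(n_win, mean)
    lam = np.repeat(win_means, window)[:length]
    return rng.poisson(lam).astype(np.int64)


def generate_dataset(config: SyntheticConfig, out_dir) -> SyntheticDataset:
    """Simulate and write a complete synthetic dataset; reproducible from the seed."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(np.random.PCG64(config.seed))
    k = config.n_diploids
    n_in_haps = 4 * k
    south, north, out_name = config.sample_names()
    samples = south + north

    # --- genealogies and mutations -------------------------------------
    mu_seg = config.mu
    used: dict[int, list] = {}  # pos -> list of carrier sets (mutation order)
    n_collisions = n_kept_multi = 0
    seg = config.segment_bp
    for seg_start in range(0, config.region_length, seg):
        seg_len = min(seg, config.region_length - seg_start)
        branches = _simulate_segment_branches(config, rng)
        L_total = sum(b for _, b in branches)
        n_mut = rng.poisson(mu_seg * seg_len * L_total)
        if n_mut == 0:
            continue
        w = np.array([b for _, b in branches])
        picks = rng.choice(len(branches), size=n_mut, p=w / w.sum())
        for b_idx in picks:
            carriers = branches[int(b_idx)][0]
            for _attempt in range(100):
                pos = seg_start + int(rng.integers(seg_len))
                if pos not in used:
                    used[pos] = [carriers]
                    break
                n_collisions += 1
                if rng.random() < config.multihit_keep:
                    used[pos].append(carriers)
                    n_kept_multi += 1
                    break

    # --- records ---------------------------------------------------------
    vcf_rows: list[str] = []
    outgroup_rows: list[OutgroupObservation] = []
    depth_out = _depth_track(
        config.region_length, config.outgroup_coverage_mean, config.coverage_cv, rng
    )
    n_records = n_multiallelic = 0
    truth_derived: dict[int, frozenset] = {}
    for pos in sorted(used):
        muts = used[pos]
        alleles = rng.choice(4, size=len(muts) + 1, replace=False)
        ref = _BASES[alleles[0]]
        alts = [_BASES[a] for a in alleles[1:]]
        hap_allele = np.zeros(n_in_haps + 2, dtype=np.int64)
        for j, carriers in enumerate(muts, start=1):
            for h in carriers:
                hap_allele[h] = j
        in_alleles = hap_allele[:n_in_haps]
        out_hap_bases = [
            ref if a == 0 else alts[a - 1] for a in hap_allele[n_in_haps:]
        ]

        # outgroup pileup observation at every mutated position
        cov = int(depth_out[pos])
        if cov > 0:
            reads = rng.integers(2, size=cov)
            seen = sorted({out_hap_bases[r] for r in reads})
        else:
            seen = []
        outgroup_rows.append(
            OutgroupObservation(
                chrom=config.chrom,
                pos=pos + 1,
                alleles=frozenset(seen),
                coverage=cov,
            )
        )

        if (in_alleles != 0).any():
            gts = []
            for i in range(2 * k):
                a1, a2 = int(in_alleles[2 * i]), int(in_alleles[2 * i + 1])
                gts.append(f"{min(a1, a2)}/{max(a1, a2)}")
            alt_field = ",".join(alts)
            vcf_rows.append(
                f"{config.chrom}\t{pos + 1}\t.\t{ref}\t{alt_field}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
            )
            n_records += 1
            if len(muts) > 1:
                n_multiallelic += 1
            elif len(muts) == 1:
                truth_derived[pos + 1] = muts[0]

    vcf_path = os.path.join(out_dir, "sites.vcf")
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            f"##contig=<ID={config.chrom},length={config.region_length}>\n"
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        fh.write("\n".join(vcf_rows))
        if vcf_rows:
            fh.write("\n")

    # --- depth tracks ----------------------------------------------------
    depth = {
        s: _depth_track(config.region_length, config.coverage_mean, config.coverage_cv, rng)
        for s in samples
    }
    depth[out_name] = depth_out
    depths_path = os.path.join(out_dir, "depths.tsv")
    df = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": np.arange(config.region_length),
            **{s: depth[s] for s in samples + [out_name]},
        }
    )
    df.to_csv(depths_path, sep="\t", index=False)

    # --- exclusion BED ---------------------------------------------------
    exclude_path = os.path.join(out_dir, "exclude.bed")
    iv_len = 200
    n_iv = int(config.exclusion_density * config.region_length / iv_len)
    starts = np.sort(rng.integers(0, max(1, config.region_length - iv_len), size=n_iv))
    from .io_formats import merge_intervals

    exclude = (
        merge_intervals(np.stack([starts, starts + iv_len], axis=1))
        if n_iv
        else np.zeros((0, 2), dtype=np.int64)
    )
    write_bed({config.chrom: exclude}, exclude_path)

    outgroup_path = os.path.join(out_dir, "outgroup.tsv")
    write_outgroup_table(outgroup_rows, outgroup_path)

    # --- manifest --------------------------------------------------------
    p = config.params
    expected_d_a_clock = 2 * config.mu * p.T
    expected_d_a_exact = 2 * config.mu * (p.T + 2 * p.N_anc - p.N_south - p.N_north)
    manifest = {
        "seed": config.seed,
        "truth": {
            "model": p.model,
            "N_anc": p.N_anc,
            "N_south": p.N_south,
            "N_north": p.N_north,
            "T": p.T,
            "m_e": p.m_e,
            "outgroup_split": config.t_outgroup,
            "mu": config.mu,
        },
        "region_length": config.region_length,
        "samples": {"south": south, "north": north, "outgroup": out_name},
        "expected_d_a_clock": expected_d_a_clock,
        "expected_d_a_exact": expected_d_a_exact,
        "expected_block_count_upper": config.region_length // 64,
        "n_records": n_records,
        "n_multiallelic": n_multiallelic,
        "n_position_collisions": n_collisions,
        "n_multihit_kept": n_kept_multi,
    }
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return SyntheticDataset(
        config=config,
        vcf_path=vcf_path,
        depths_path=depths_path,
        exclude_bed_path=exclude_path,
        outgroup_path=outgroup_path,
        manifest_path=manifest_path,
        manifest=manifest,
        n_records=n_records,
        n_multiallelic=n_multiallelic,
    )
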