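"""Pipeline orchestration: mask -> blocks -> bSFS -> fit -> bootstrap -> stats.

Every stage is a pure function of its declared inputs plus the seed, writes
its outputs under the configured output directory, and is recorded in a run
manifest with input/output SHA-256 hashes so that a rerun with identical
configuration can be verified hash-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .blocks import (
    BlockSpec,
    BSFSTable,
    aggregate_bsfs,
    apply_kmax,
    cut_blocks,
    tally_block,
)
from .inference import LikelihoodOptions, MutationModel, fit_model
from .io_formats import (
    CallableMask,
    build_callable_mask,
    parse_vcf_biallelic,
    polarize_with_outgroup,
    read_bed,
    read_outgroup_table,
    subtract_annotation,
    subtract_intervals,
)
from .model_selection import derive_seeds, parametric_bootstrap
from .sumstats import (
    SFSSpectrum,
    distance_to_outgroup_extra,
    diversity_divergence,
    divergence_time_years,
    fst_scan,
    net_divergence,
    outgroup_divergence,
    relative_node_depth,
    sfs_neutrality_stats,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    vcf: str
    depths: str
    outdir: str
    exclude_bed: str | None = None
    outgroup_table: str | None = None
    sample_map: dict[str, str] = field(default_factory=dict)
    block_spec: BlockSpec = field(default_factory=BlockSpec)
    mut: MutationModel = field(default_factory=MutationModel)
    models: tuple[str, ...] = ("SI",)
    n_genealogies: int = 2000
    max_iter: int = 1000
    bootstrap_replicates: int = 0  # 0 disables the bootstrap stage
    bootstrap_im_model: str = "IM2"
    maf_min: float = 0.1
    fst_window: int = 10_000
    gen_years: float = 1.7
    min_cov: int = 8
    sd_mult: float = 0.75
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "block_spec" in raw:
            raw["block_spec"] = BlockSpec(**raw["block_spec"])
        if "mut" in raw:
            raw["mut"] = MutationModel(**raw["mut"])
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)


@dataclass
class RunManifest:
    stages: list[dict] = field(default_factory=list)
    seed: int = 0
    version: str = __version__

    def add(self, name: str, inputs: list[str], outputs: list[str], wall: float,
            status: str = "ok", message: str = "") -> None:
        self.stages.append(
            {
                "stage": name,
                "inputs": {os.path.basename(p): _sha256(p) for p in inputs},
                "outputs": {os.path.basename(p): _sha256(p) for p in outputs},
                "wall_seconds": round(wall, 3),
                "status": status,
                "message": message,
            }
        )

    def to_dict(self) -> dict:
        out_names = [n for s in self.stages for n in s["outputs"]]
        if len(out_names) != len(set(out_names)):
            raise PipelineError("manifest lists an output file more than once")
        return {"seed": self.seed, "version": self.version, "stages": self.stages}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_depths(path) -> dict[str, dict[str, np.ndarray]]:
    df = pd.read_csv(path, sep="\t")
    samples = [c for c in df.columns if c not in ("chrom", "pos")]
    out: dict[str, dict[str, np.ndarray]] = {s: {} for s in samples}
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        for s in samples:
            out[s][str(chrom)] = sub[s].to_numpy()
    return out


def _positions_in_mask(pos0: np.ndarray, iv: np.ndarray) -> np.ndarray:
    """Boolean: which 0-based positions fall inside sorted half-open intervals."""
    if len(iv) == 0:
        return np.zeros(len(pos0), dtype=bool)
    i = np.searchsorted(iv[:, 0], pos0, side="right") - 1
    ok = i >= 0
    ok[ok] &= pos0[ok] < iv[i[ok], 1]
    return ok


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all configured stages in dependency order.

    Returns the manifest; raises :class:`PipelineError` (after writing the
    manifest with the failed stage recorded) on any stage failure.
    """
    manifest = RunManifest(seed=config.seed)
    os.makedirs(config.outdir, exist_ok=True)
    manifest_path = os.path.join(config.outdir, "run_manifest.json")

    def fail(stage: str, msg: str) -> PipelineError:
        manifest.add(stage, [], [], 0.0, status="failed", message=msg)
        manifest.write(manifest_path)
        return PipelineError(f"stage {stage!r} failed: {msg}")

    for p, label in ((config.vcf, "vcf"), (config.depths, "depths")):
        if not os.path.exists(p):
            raise fail("inputs", f"missing {label} file: {p}")

    state: dict = {}
    stages = [
        ("mask", _stage_mask),
        ("blocks", _stage_blocks),
        ("tally", _stage_tally),
        ("fit", _stage_fit),
    ]
    if config.bootstrap_replicates > 0:
        stages.append(("bootstrap", _stage_bootstrap))
    stages.append(("stats", _stage_stats))

    for name, fn in stages:
        t0 = time.time()
        try:
            inputs, outputs = fn(config, state)
        except PipelineError:
            raise
        except Exception as exc:
            logger.exception("stage %s failed", name)
            raise fail(name, str(exc))
        manifest.add(name, inputs, outputs, time.time() - t0)
        logger.info("stage %s ok (%.1fs)", name, time.time() - t0)

    manifest.write(manifest_path)
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_mask(config: PipelineConfig, state: dict):
    depths = _read_depths(config.depths)
    mask = build_callable_mask(depths, min_cov=config.min_cov, sd_mult=config.sd_mult)
    inputs = [config.depths]
    if config.exclude_bed and os.path.exists(config.exclude_bed):
        mask = subtract_annotation(mask, read_bed(config.exclude_bed))
        inputs.append(config.exclude_bed)
    out = os.path.join(config.outdir, "callable_mask.bed")
    mask.to_bed(out)
    state["mask"] = mask
    return inputs, [out]


def _pairs(config: PipelineConfig) -> list[tuple[str, str]]:
    south = sorted(s for s, p in config.sample_map.items() if p == "south")
    north = sorted(s for s, p in config.sample_map.items() if p == "north")
    if not south or not north:
        raise ValueError("sample_map must assign at least one sample per population")
    return [(s, n) for s in south for n in north]


def _stage_blocks(config: PipelineConfig, state: dict):
    vcf_data = parse_vcf_biallelic(config.vcf, config.sample_map)
    state["vcf"] = vcf_data
    mask: CallableMask = state["mask"]
    spec = config.block_spec

    # per-pair joint masks with missing-genotype positions removed
    sample_col = {s: i for i, s in enumerate(vcf_data.samples)}
    blocks_by_pair = {}
    for s, n in _pairs(config):
        pair_mask = mask.pair_intersection(s, n)
        miss: dict[str, list[int]] = {}
        for site in vcf_data.sites:
            if (
                site.genotypes[sample_col[s]] is None
                or site.genotypes[sample_col[n]] is None
            ):
                miss.setdefault(site.chrom, []).append(site.pos0)
        for chrom, positions in miss.items():
            if chrom in pair_mask:
                drop = np.array([[p, p + 1] for p in sorted(positions)])
                pair_mask[chrom] = subtract_intervals(pair_mask[chrom], drop)
        blocks_by_pair[(s, n)] = cut_blocks(pair_mask, spec, pair=f"{s}-{n}")

    out = os.path.join(config.outdir, "blocks.tsv")
    with open(out, "w") as fh:
        fh.write("chrom\tstart\tend\tpair\tn_callable\n")
        for pair in sorted(blocks_by_pair):
            for b in blocks_by_pair[pair]:
                fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.pair}\t{len(b.positions)}\n")
    state["blocks"] = blocks_by_pair
    return [config.vcf], [out]


def _stage_tally(config: PipelineConfig, state: dict):
    vcf_data = state["vcf"]
    spec = config.block_spec
    sample_col = {s: i for i, s in enumerate(vcf_data.samples)}
    configs = []
    for (s, n), blocks in sorted(state["blocks"].items()):
        ia, ib = sample_col[s], sample_col[n]
        lookup_by_chrom: dict[str, dict[int, tuple]] = {}
        for site in vcf_data.sites:
            ga, gb = site.genotypes[ia], site.genotypes[ib]
            if ga is None or gb is None:
                continue
            lookup_by_chrom.setdefault(site.chrom, {})[site.pos0] = (ga, gb)
        for b in blocks:
            cfg = tally_block(b, lookup_by_chrom.get(b.chrom, {}))
            configs.append(apply_kmax(cfg, spec.kmax))
    bsfs = aggregate_bsfs(configs, spec)
    out = os.path.join(config.outdir, "bsfs.tsv")
    bsfs.to_tsv(out)
    state["bsfs"] = bsfs
    return [], [out]


def _stage_fit(config: PipelineConfig, state: dict):
    bsfs: BSFSTable = state["bsfs"]
    seeds = derive_seeds(config.seed, len(config.models), stream=10)
    outputs = []
    state["fits"] = {}
    for model, s in zip(config.models, seeds):
        opts = LikelihoodOptions(
            n_genealogies=config.n_genealogies, seed=s, kmax=config.block_spec.kmax
        )
        fit = fit_model(bsfs, model, config.mut, opts, max_iter=config.max_iter)
        out = os.path.join(config.outdir, f"fit_{model}.json")
        with open(out, "w") as fh:
            json.dump(fit.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        state["fits"][model] = fit
        outputs.append(out)
    return [], outputs


def _stage_bootstrap(config: PipelineConfig, state: dict):
    fits = state["fits"]
    if "SI" not in fits:
        raise ValueError("bootstrap requires an SI fit")
    im_model = config.bootstrap_im_model
    observed = fits[im_model].cl - fits["SI"].cl if im_model in fits else None
    bsfs: BSFSTable = state["bsfs"]
    opts = LikelihoodOptions(
        n_genealogies=config.n_genealogies, seed=config.seed, kmax=config.block_spec.kmax
    )
    result = parametric_bootstrap(
        fits["SI"],
        im_model,
        n_blocks=bsfs.total,
        mut=config.mut,
        opts=opts,
        seed=derive_seeds(config.seed, 1, stream=20)[0],
        n_replicates=config.bootstrap_replicates,
        observed_delta_cl=observed,
        max_iter=config.max_iter,
    )
    out = os.path.join(config.outdir, "bootstrap.json")
    with open(out, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    state["bootstrap"] = result
    return [], [out]


def _stage_stats(config: PipelineConfig, state: dict):
    vcf_data = state["vcf"]
    mask: CallableMask = state["mask"]

    south_idx = [i for i, p in enumerate(vcf_data.populations) if p == "south"]
    north_idx = [i for i, p in enumerate(vcf_data.populations) if p == "north"]
    ingroup = [vcf_data.samples[i] for i in south_idx + north_idx]

    # joint callable region of all in-group samples; sites restricted to it
    joint: dict[str, np.ndarray] = {}
    chroms = set.intersection(*(set(mask.intervals[s]) for s in ingroup))
    for chrom in sorted(chroms):
        iv = mask.get(ingroup[0], chrom)
        for s in ingroup[1:]:
            from .io_formats import intersect_intervals

            iv = intersect_intervals(iv, mask.get(s, chrom))
        joint[chrom] = iv
    n_callable = int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in joint.values()))
    if n_callable == 0:
        raise ValueError("no jointly callable sites")

    pos_ok = []
    for site in vcf_data.sites:
        iv = joint.get(site.chrom, np.zeros((0, 2), dtype=np.int64))
        pos_ok.append(bool(_positions_in_mask(np.array([site.pos0]), iv)[0]))
    sites = [s for s, ok in zip(vcf_data.sites, pos_ok) if ok]

    pi_s, pi_n, dxy = diversity_divergence(sites, south_idx, north_idx, n_callable)
    d_a = net_divergence(dxy, pi_s, pi_n)
    t_years = divergence_time_years(max(d_a, 0.0), config.mut.mu, config.gen_years)

    rnd = None
    inputs = []
    stats: dict = {}
    if config.outgroup_table and os.path.exists(config.outgroup_table):
        inputs.append(config.outgroup_table)
        og = read_outgroup_table(config.outgroup_table)
        cov = np.array([o.coverage for o in og.values()], dtype=float)
        mean_cov = float(cov.mean()) if len(cov) else 0.0
        pol = polarize_with_outgroup(sites, og, mean_cov) if mean_cov > 0 else []
        anc = {
            (p.site.chrom, p.site.pos): p.ancestral
            for p in pol
            if p.status == "polarized"
        }
        vcf_positions = {(s.chrom, s.pos) for s in vcf_data.sites}
        # restrict outgroup-only rows to the same callable region as the
        # denominator, else outgroup divergence is inflated by masked sites
        og_masked = {
            key: obs
            for key, obs in og.items()
            if obs.chrom in joint
            and _positions_in_mask(np.array([obs.pos - 1]), joint[obs.chrom])[0]
        }
        extra = distance_to_outgroup_extra(og_masked, vcf_positions, mean_cov / 3.0)
        d_out_s = outgroup_divergence(sites, south_idx, anc, n_callable, extra_fixed=extra)
        d_out_n = outgroup_divergence(sites, north_idx, anc, n_callable, extra_fixed=extra)
        if d_out_s > 0 and d_out_n > 0:
            rnd = relative_node_depth(dxy, d_out_s, d_out_n)
        stats["d_out_south"] = d_out_s
        stats["d_out_north"] = d_out_n

        # derived-allele spectra and neutrality statistics per population
        for label, idx in (("south", south_idx), ("north", north_idx)):
            n_hap = 2 * len(idx)
            counts = [0] * (n_hap - 1)
            for p in pol:
                if p.status != "polarized":
                    continue
                gts = [p.site.genotypes[i] for i in idx]
                if any(g is None for g in gts):
                    continue
                alt = sum(g[0] + g[1] for g in gts)
                der = alt if p.ancestral == "ref" else n_hap - alt
                if 0 < der < n_hap:
                    counts[der - 1] += 1
            spec = SFSSpectrum(n=n_hap, counts=tuple(counts))
            d, h = sfs_neutrality_stats(spec)
            stats[f"tajimas_d_{label}"] = d
            stats[f"fay_wu_h_{label}"] = h
            stats[f"S_{label}"] = spec.S

    per_site, windows = fst_scan(
        sites, south_idx, north_idx, maf_min=config.maf_min, window=config.fst_window
    )
    fst_out = os.path.join(config.outdir, "fst_windows.tsv")
    with open(fst_out, "w") as fh:
        fh.write("chrom\tstart\tend\tfst_weighted\tn_sites\n")
        for w in windows:
            val = "NA" if w.value is None else f"{w.value:.6f}"
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{val}\t{w.n_sites}\n")
    used = [v for v in per_site if v is not None]
    stats.update(
        {
            "pi_south": pi_s,
            "pi_north": pi_n,
            "dxy": dxy,
            "d_a": d_a,
            "rnd": rnd,
            "t_years": t_years,
            "n_callable": n_callable,
            "n_sites_used": len(sites),
            "fst_mean_site": float(np.mean(used)) if used else None,
            "fst_windows": len(windows),
        }
    )
    out = os.path.join(config.outdir, "stats.json")
    with open(out, "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
        fh.write("\n")
    state["stats"] = stats
    return inputs, [out, fst_out]
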