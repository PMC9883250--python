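"""Validation experiments over the inference machinery.

These are the study-design checks run by the analysis scripts: the analytic
branch-length oracle, probability normalization, parameter recovery on
simulated truth, type-I-error calibration of the parametric-bootstrap model
test, and whole-pipeline determinism.  Each function is deterministic given
its seed and returns a plain dict so drivers can dump results straight to
JSON.
"""

from __future__ import annotations

import hashlib
import os

import numpy as np

from .blocks import BlockSpec, aggregate_bsfs, configs_from_array
from .coalescent import (
    ModelParams,
    panmictic_expected_lengths,
    sample_branch_lengths,
    simulate_block_configs,
)
from .inference import (
    LikelihoodOptions,
    MutationModel,
    composite_log_likelihood,
    config_log_prob,
    fit_model,
)
from .model_selection import derive_seeds, parametric_bootstrap

__all__ = [
    "branch_class_experiment",
    "normalization_experiment",
    "recovery_experiment",
    "calibration_experiment",
    "determinism_experiment",
    "RECOVERY_TRUTH",
]

# recovery-experiment truth: ancestral size below, northern size above, the
# contemporary southern size, with a split deep enough that all four
# mutation classes are informative
RECOVERY_TRUTH = ModelParams("SI", N_anc=2e5, N_south=3e5, N_north=9e5, T=7e5)


def branch_class_experiment(
    N: float = 1e4, n: int = 100_000, seed: int = 0
) -> dict:
    """Monte Carlo means of the four branch classes at T=0 vs the closed form.

    For four lineages in a panmictic population the expected class lengths
    are (8N/3, 8N/3, 4N/3, 2N/3); reports the z-score of each Monte Carlo
    mean against its standard error.
    """
    rng = np.random.default_rng(np.random.PCG64(seed))
    L = sample_branch_lengths(ModelParams("SI", N, N, N, 0.0), n, rng)
    expect = panmictic_expected_lengths(N).as_array()
    mean = L.mean(axis=0)
    se = L.std(axis=0, ddof=1) / np.sqrt(n)
    z = (mean - expect) / se
    return {
        "n": n,
        "mean": mean.tolist(),
        "expected": expect.tolist(),
        "z": z.tolist(),
        "max_abs_z": float(np.max(np.abs(z))),
    }


def normalization_experiment(
    params: ModelParams | None = None,
    n_genealogies: int = 400,
    seed: int = 0,
    kmax: int = 2,
    u_block: float | None = None,
) -> dict:
    """Total probability of the capped configuration space for one genealogy sample."""
    import itertools

    params = params or RECOVERY_TRUTH
    u = u_block if u_block is not None else MutationModel().u_block
    rng = np.random.default_rng(np.random.PCG64(seed))
    L = sample_branch_lengths(params, n_genealogies, rng)
    total = 0.0
    for vals in itertools.product(range(kmax + 2), repeat=4):
        from .blocks import MutationConfig

        cfg = MutationConfig(*vals, capped=tuple(v == kmax + 1 for v in vals))
        total += np.exp(config_log_prob(cfg, L, u, kmax, floor=False))
    return {"n": n_genealogies, "total_probability": float(total)}


def recovery_experiment(
    truth: ModelParams | None = None,
    n_blocks: int = 30_000,
    n_genealogies: int = 6000,
    max_iter: int = 1000,
    seed: int = 0,
    mut: MutationModel | None = None,
) -> dict:
    """Simulate a bSFS under known truth, refit, report relative errors."""
    truth = truth or RECOVERY_TRUTH
    mut = mut or MutationModel()
    s_sim, s_fit = derive_seeds(seed, 2, stream=3)
    rng = np.random.default_rng(np.random.PCG64(s_sim))
    counts = simulate_block_configs(
        truth, mut.u_block, n_blocks, rng, block_span=mut.block_span
    )
    bsfs = aggregate_bsfs(configs_from_array(counts, 2), BlockSpec())
    fit = fit_model(
        bsfs, truth.model, mut,
        LikelihoodOptions(n_genealogies, s_fit), max_iter=max_iter,
    )
    rel = {
        k: (getattr(fit.params, k) - getattr(truth, k)) / getattr(truth, k)
        for k in ("N_anc", "N_south", "N_north", "T")
    }
    return {
        "n": n_blocks,
        "truth": {k: getattr(truth, k) for k in ("N_anc", "N_south", "N_north", "T")},
        "estimate": {
            k: getattr(fit.params, k) for k in ("N_anc", "N_south", "N_north", "T")
        },
        "relative_error": rel,
        "T_rel_error": rel["T"],
        "cl": fit.cl,
        "n_iter": fit.n_iter,
    }


def calibration_experiment(
    truth: ModelParams | None = None,
    n_outer: int = 20,
    n_replicates: int = 25,
    n_blocks: int = 3000,
    n_genealogies: int = 300,
    max_iter: int = 100,
    im_model: str = "IM2",
    alpha: float = 0.05,
    seed: int = 0,
    mut: MutationModel | None = None,
) -> dict:
    """Type-I-error calibration of the parametric-bootstrap CL-improvement test.

    Outer data are simulated under a strict-isolation truth, so rejections
    are false positives; with the add-one p-value and ``n_replicates`` null
    draws the nominal rate at alpha=0.05 is at most 1/(n_replicates+1) under
    exchangeability of observed and null CL improvements.
    """
    truth = truth or RECOVERY_TRUTH
    mut = mut or MutationModel()
    p_values = []
    for i in range(n_outer):
        s_sim, s_si, s_im, s_boot = derive_seeds(seed, 4, stream=100 + i)
        rng = np.random.default_rng(np.random.PCG64(s_sim))
        counts = simulate_block_configs(
            truth, mut.u_block, n_blocks, rng, block_span=mut.block_span
        )
        bsfs = aggregate_bsfs(configs_from_array(counts, 2), BlockSpec())
        f_si = fit_model(
            bsfs, "SI", mut, LikelihoodOptions(n_genealogies, s_si), max_iter=max_iter
        )
        f_im = fit_model(
            bsfs, im_model, mut, LikelihoodOptions(n_genealogies, s_im),
            max_iter=max_iter,
        )
        boot = parametric_bootstrap(
            f_si, im_model, n_blocks=n_blocks, mut=mut,
            opts=LikelihoodOptions(n_genealogies, 0), seed=s_boot,
            n_replicates=n_replicates, observed_delta_cl=f_im.cl - f_si.cl,
            max_iter=max_iter,
        )
        p_values.append(boot.p_value)
    rejections = sum(1 for p in p_values if p <= alpha)
    return {
        "n": n_outer,
        "n_replicates": n_replicates,
        "p_values": p_values,
        "rejections": rejections,
        "rejection_rate": rejections / n_outer,
    }


def determinism_experiment(base_dir, seed: int = 0, region_length: int = 60_000) -> dict:
    """Generate data and run the full pipeline twice; compare output hashes.

    The run manifest is excluded from the comparison because it records
    wall-clock times.
    """
    from .pipeline import PipelineConfig, run_pipeline
    from .synthetic import SyntheticConfig, generate_dataset

    def one_run(tag: str) -> dict[str, str]:
        data_dir = os.path.join(base_dir, f"data_{tag}")
        run_dir = os.path.join(base_dir, f"run_{tag}")
        ds = generate_dataset(
            SyntheticConfig(region_length=region_length, seed=seed), data_dir
        )
        cfg = PipelineConfig(
            vcf=ds.vcf_path,
            depths=ds.depths_path,
            outdir=run_dir,
            exclude_bed=ds.exclude_bed_path,
            outgroup_table=ds.outgroup_path,
            sample_map={"S1": "south", "S2": "south", "N1": "north", "N2": "north"},
            models=("SI",),
            n_genealogies=300,
            max_iter=40,
            seed=seed,
        )
        run_pipeline(cfg)
        hashes = {}
        for d in (data_dir, run_dir):
            for name in sorted(os.listdir(d)):
                if name == "run_manifest.json":
                    continue
                with open(os.path.join(d, name), "rb") as fh:
                    hashes[name] = hashlib.sha256(fh.read()).hexdigest()
        return hashes

    h1 = one_run("a")
    h2 = one_run("b")
    return {
        "n": len(h1),
        "identical": h1 == h2,
        "files": sorted(h1),
    }
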