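"""Composite-likelihood inference from the blockwise site frequency spectrum.

The probability of a block's mutation configuration is approximated by Monte
Carlo: a sample of genealogies is drawn under the candidate demographic
parameters and, for each genealogy, the four per-type mutation counts are
independent Poisson with mean ``u_block * L_type``; averaging the product
over genealogies integrates out the unknown genealogy.  Counts capped at
``kmax`` use the Poisson upper-tail probability, so the capped configuration
space has total probability exactly 1 for any genealogy sample.

The composite log-likelihood of a bSFS table treats blocks as independent.
It is maximized with Nelder-Mead on log10-transformed parameters.  Common
random numbers — the same genealogy seed reused for every evaluation within
one fit — make the Monte Carlo likelihood surface deterministic, which
Nelder-Mead requires to terminate sensibly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import Bounds, minimize
from scipy.special import gammaln, pdtrc

from .blocks import BSFSTable, MutationConfig
from .coalescent import MODELS, BranchLengths, ModelParams, sample_branch_lengths

logger = logging.getLogger(__name__)

__all__ = [
    "MutationModel",
    "LikelihoodOptions",
    "FitResult",
    "DEFAULT_BOUNDS",
    "config_log_prob",
    "composite_log_likelihood",
    "fit_model",
    "moment_start",
]


@dataclass(frozen=True)
class MutationModel:
    """Per-site mutation rate and block span; ``u_block = mu * block_span``."""

    mu: float = 4.6e-9
    block_span: int = 64

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")

    @property
    def u_block(self) -> float:
        return self.mu * self.block_span


@dataclass(frozen=True)
class LikelihoodOptions:
    """Monte Carlo settings for one likelihood evaluation."""

    n_genealogies: int = 4000
    seed: int = 0
    kmax: int = 2

    def __post_init__(self) -> None:
        if self.n_genealogies < 100:
            raise ValueError("n_genealogies must be >= 100")


# log10-scale default box constraints: sizes and T in [1e3, 1e7], m_e in [1e-9, 1e-4]
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "N_anc": (1e3, 1e7),
    "N_south": (1e3, 1e7),
    "N_north": (1e3, 1e7),
    "T": (1e3, 1e7),
    "m_e": (1e-9, 1e-4),
}


@dataclass
class FitResult:
    model: str
    params: ModelParams
    cl: float
    n_iter: int
    converged: bool
    bounds: dict[str, tuple[float, float]]
    seed: int
    n_floored: int = 0

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": {
                "N_anc": self.params.N_anc,
                "N_south": self.params.N_south,
                "N_north": self.params.N_north,
                "T": self.params.T,
                "m_e": self.params.m_e,
            },
            "cl": self.cl,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "seed": self.seed,
            "n_floored": self.n_floored,
        }


def _type_prob_table(lam: np.ndarray, kmax: int) -> np.ndarray:
    """Per-genealogy per-type Poisson probabilities for counts 0..kmax and the tail.

    ``lam`` is (n, 4); returns (n, 4, kmax + 2) where slot ``kmax + 1`` holds
    P(K > kmax).
    """
    n = lam.shape[0]
    tab = np.empty((n, 4, kmax + 2))
    log_lam = np.log(np.maximum(lam, 1e-300))
    for k in range(kmax + 1):
        logp = -lam + k * log_lam - gammaln(k + 1)
        pk = np.exp(logp)
        if k > 0:
            pk[lam == 0] = 0.0
        tab[:, :, k] = pk
    tab[:, :, kmax + 1] = pdtrc(kmax, lam)
    return tab


def _config_indices(cfg: np.ndarray, capped: np.ndarray, kmax: int) -> np.ndarray:
    """Map configuration rows to probability-table slots (capped -> tail slot)."""
    idx = np.asarray(cfg, dtype=np.int64).copy()
    idx[np.asarray(capped, dtype=bool)] = kmax + 1
    if (idx < 0).any() or (idx > kmax + 1).any():
        raise ValueError("configuration counts exceed kmax without capped flag")
    return idx


def _log_probs(
    tab: np.ndarray, cfg: np.ndarray, capped: np.ndarray, kmax: int, floor: bool = True
) -> tuple[np.ndarray, int]:
    """Genealogy-averaged log probability for each configuration row.

    With ``floor=False`` a configuration with zero Monte Carlo mass gets
    ``-inf`` (its exact probability under the sampled genealogies), keeping
    the capped configuration space normalized; with ``floor=True`` it gets
    the pseudo-floor ``log(1/(n+1))`` so composite likelihoods stay finite.
    """
    n_gen = tab.shape[0]
    idx = _config_indices(cfg, capped, kmax)
    w = (
        tab[:, 0, idx[:, 0]]
        * tab[:, 1, idx[:, 1]]
        * tab[:, 2, idx[:, 2]]
        * tab[:, 3, idx[:, 3]]
    )  # (n_gen, k)
    p = w.mean(axis=0)
    floored = p <= 0.0
    n_floored = int(floored.sum())
    if floor:
        p = np.where(floored, 1.0 / (n_gen + 1), p)
    with np.errstate(divide="ignore"):
        return np.log(p), n_floored


def config_log_prob(
    config: MutationConfig,
    genealogies: np.ndarray | list[BranchLengths],
    u_block: float,
    kmax: int,
    return_flag: bool = False,
    floor: bool = True,
):
    """Log probability of one capped configuration given a genealogy sample.

    The probability is the genealogy average of the product over the four
    mutation types of Poisson(k; u_block * L_type); capped entries use the
    Poisson upper tail P(K > kmax).  A configuration with zero Monte Carlo
    mass receives the pseudo-floor log(1 / (n + 1)) and is flagged — unless
    ``floor=False``, in which case it keeps probability zero (``-inf`` log),
    which is the convention under which the capped configuration space sums
    to exactly 1.
    """
    L = _as_length_array(genealogies)
    if L.shape[0] < 1:
        raise ValueError("need at least one genealogy")
    tab = _type_prob_table(u_block * L, kmax)
    cfg = np.array([config.counts()])
    cap = np.array([config.capped])
    logp, n_floored = _log_probs(tab, cfg, cap, kmax, floor=floor)
    if n_floored:
        logger.debug("configuration %s has zero Monte Carlo mass", config)
    if return_flag:
        return float(logp[0]), bool(n_floored)
    return float(logp[0])


def _as_length_array(genealogies) -> np.ndarray:
    if isinstance(genealogies, np.ndarray):
        return genealogies.reshape(-1, 4)
    return np.array([g.as_array() for g in genealogies]).reshape(-1, 4)


def composite_log_likelihood(
    bsfs: BSFSTable,
    params: ModelParams,
    mut: MutationModel,
    opts: LikelihoodOptions,
    _genealogies: np.ndarray | None = None,
) -> float:
    """Composite log-likelihood of a bSFS table under a demographic model.

    One shared genealogy sample (drawn from ``opts.seed``) is used for every
    configuration, so the value is deterministic given the options.
    """
    if bsfs.total == 0:
        return 0.0
    cfg, cap, n = bsfs.as_arrays()
    if _genealogies is None:
        rng = np.random.default_rng(np.random.PCG64(opts.seed))
        L = sample_branch_lengths(params, opts.n_genealogies, rng)
    else:
        L = _genealogies
    tab = _type_prob_table(mut.u_block * L, opts.kmax)
    logp, _ = _log_probs(tab, cfg, cap, opts.kmax)
    return float((n * logp).sum())


def moment_start(
    bsfs: BSFSTable,
    model: str,
    mut: MutationModel,
    bounds: dict[str, tuple[float, float]],
) -> ModelParams:
    """Method-of-moments starting point.

    Contemporary sizes from the mean singleton-type counts (E[L_hetX] -> 4N
    for long splits), the split time from the mean fixed count
    (E[L_fixed] ~ 2T), and the ancestral size from the mean shared-het count
    (panmictic E[L_hetAB] = 4N/3).  Crude on purpose; it only needs to land
    in the likelihood basin.
    """
    m = bsfs.mean_counts()
    u = mut.u_block

    def clip(name: str, v: float) -> float:
        lo, hi = bounds[name]
        return float(np.clip(v if np.isfinite(v) and v > 0 else lo, lo, hi))

    N_s = clip("N_south", m[0] / (4 * u))
    N_n = clip("N_north", m[1] / (4 * u))
    T = clip("T", m[3] / (2 * u))
    N_a = clip("N_anc", 3 * m[2] / (4 * u) if m[2] > 0 else (N_s + N_n) / 2)
    m_e = 0.0 if model == "SI" else float(np.sqrt(bounds["m_e"][0] * bounds["m_e"][1]))
    return ModelParams(model, N_anc=N_a, N_south=N_s, N_north=N_n, T=T, m_e=m_e)


def _param_names(model: str) -> list[str]:
    names = ["N_anc", "N_south", "N_north", "T"]
    if model != "SI":
        names.append("m_e")
    return names


def _to_params(model: str, values: np.ndarray, names: list[str]) -> ModelParams:
    d = dict(zip(names, (float(v) for v in values)))
    return ModelParams(
        model,
        N_anc=d["N_anc"],
        N_south=d["N_south"],
        N_north=d["N_north"],
        T=d["T"],
        m_e=d.get("m_e", 0.0),
    )


def fit_model(
    bsfs: BSFSTable,
    model: str,
    mut: MutationModel,
    opts: LikelihoodOptions,
    start: ModelParams | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    max_iter: int = 1000,
) -> FitResult:
    """Maximize the composite likelihood with Nelder-Mead.

    Parameters are optimized on log10 scale within box bounds.  Termination:
    relative composite-likelihood change below 1e-6 (via the simplex
    function-value tolerance) or ``max_iter`` iterations, whichever first.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    bounds = dict(bounds or {k: DEFAULT_BOUNDS[k] for k in _param_names(model)})
    names = _param_names(model)
    all_bounds = {**DEFAULT_BOUNDS, **bounds}
    lo = np.log10([bounds[k][0] for k in names])
    hi = np.log10([bounds[k][1] for k in names])

    if start is not None:
        starts = [start]
    else:
        # the moment start can land in a compensating T-vs-N_anc basin; probe
        # a few deterministic variants and polish the best
        base = moment_start(bsfs, model, mut, all_bounds)
        d = {k: getattr(base, k) for k in names}
        mid = float(np.clip((base.N_south + base.N_north) / 2,
                            bounds["N_anc"][0], bounds["N_anc"][1]))
        starts = [base]
        starts.append(_to_params(model, np.array([mid if k == "N_anc" else d[k] for k in names]), names))
        starts.append(
            _to_params(
                model,
                np.array([
                    mid if k == "N_anc" else (d["T"] / 2 if k == "T" else d[k])
                    for k in names
                ]),
                names,
            )
        )
    x0s = []
    for s in starts:
        x = np.log10([getattr(s, k) for k in names])
        if ((x < lo) | (x > hi)).any():
            if start is not None:
                raise ValueError("start point outside bounds")
            x = np.clip(x, lo, hi)
        x0s.append(x)
    x0 = x0s[0]

    def objective(x: np.ndarray) -> float:
        p = _to_params(model, 10.0 ** x, names)
        cl = composite_log_likelihood(bsfs, p, mut, opts)
        return -cl

    cl0 = -objective(x0)
    if not np.isfinite(cl0):
        raise ValueError(
            "composite likelihood non-finite at the start point; "
            "choose a different start"
        )
    fatol = max(1e-6 * abs(cl0), 1e-9)

    n_iter, success = 0, False
    x, fbest = x0, np.inf
    if len(x0s) > 1:
        # short probe from each candidate start; the winner gets the budget
        probe = max(20, max_iter // 8)
        for xs in x0s:
            res = minimize(
                objective, xs, method="Nelder-Mead", bounds=Bounds(lo, hi),
                options={"maxiter": probe, "maxfev": 10 * max_iter,
                         "xatol": 2e-3, "fatol": fatol},
            )
            n_iter += int(res.nit)
            if res.fun < fbest:
                x, fbest = res.x, res.fun

    # Nelder-Mead on the Monte Carlo surface can terminate in a degenerate
    # simplex; restarting from the incumbent with a fresh simplex (within the
    # same overall iteration budget) is the standard remedy.
    while n_iter < max_iter:
        res = minimize(
            objective,
            x,
            method="Nelder-Mead",
            bounds=Bounds(lo, hi),
            options={
                "maxiter": max_iter - n_iter,
                "maxfev": 10 * max_iter,
                "xatol": 2e-3,
                "fatol": fatol,
            },
        )
        n_iter += int(res.nit)
        success = bool(res.success)
        if res.fun >= fbest - fatol:
            if res.fun < fbest:
                x, fbest = res.x, res.fun
            break
        x, fbest = res.x, res.fun
    best = _to_params(model, 10.0 ** np.clip(x, lo, hi), names)
    # recompute n_floored at the optimum for the report
    cfg, cap, n = bsfs.as_arrays()
    rng = np.random.default_rng(np.random.PCG64(opts.seed))
    L = sample_branch_lengths(best, opts.n_genealogies, rng)
    tab = _type_prob_table(mut.u_block * L, opts.kmax)
    _, n_floored = _log_probs(tab, cfg, cap, opts.kmax)
    return FitResult(
        model=model,
        params=best,
        cl=float(-fbest),
        n_iter=n_iter,
        converged=success,
        bounds=bounds,
        seed=opts.seed,
        n_floored=n_floored,
    )
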