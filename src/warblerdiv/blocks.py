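"""Blockwise site-frequency-spectrum construction.

Callable sequence is cut into blocks containing a fixed number of callable
sites (default 64) whose physical span may stretch over missing data up to a
cap (default 128 bp).  For one diploid sample from each population, every
callable site in a block is classified into one of four mutation types
(hetA, hetB, hetAB, fixed) and the per-block count 4-tuples — capped at
``kmax`` mutations per type — are tallied into the blockwise site frequency
spectrum (bSFS).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "BlockSpec",
    "Block",
    "MutationConfig",
    "BSFSTable",
    "MUTATION_TYPES",
    "cut_blocks",
    "classify_site",
    "tally_block",
    "apply_kmax",
    "aggregate_bsfs",
    "configs_from_array",
]

MUTATION_TYPES = ("hetA", "hetB", "hetAB", "fixed")


@dataclass(frozen=True)
class BlockSpec:
    """Block-cutting and capping parameters.

    ``block_span`` callable sites per block, physical span limited to
    ``max_physical`` bp, per-type mutation counts capped at ``kmax``.
    """

    block_span: int = 64
    max_physical: int = 128
    kmax: int = 2

    def __post_init__(self) -> None:
        if not (1 <= self.block_span <= self.max_physical):
            raise ValueError("require 1 <= block_span <= max_physical")
        if self.kmax < 1:
            raise ValueError("kmax must be >= 1")


@dataclass(frozen=True)
class Block:
    chrom: str
    start: int  # 0-based half-open physical span
    end: int
    positions: tuple[int, ...]  # callable positions, 0-based, strictly increasing
    pair: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start > 0 and not self.positions:
            raise ValueError("non-empty block must have positions")


@dataclass(frozen=True)
class MutationConfig:
    """Per-block mutation-type counts with optional kmax capping.

    A capped field stores ``kmax + 1`` as a sentinel and sets the
    corresponding flag, meaning "more than kmax mutations of this type".
    """

    hetA: int
    hetB: int
    hetAB: int
    fixed: int
    capped: tuple[bool, bool, bool, bool] = (False, False, False, False)

    def counts(self) -> tuple[int, int, int, int]:
        return (self.hetA, self.hetB, self.hetAB, self.fixed)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts()):
            raise ValueError("mutation counts must be non-negative")


@dataclass
class BSFSTable:
    """Counts of blockwise mutation configurations."""

    counts: dict[MutationConfig, int] = field(default_factory=dict)
    total: int = 0
    spec: BlockSpec = field(default_factory=BlockSpec)

    def items_sorted(self) -> list[tuple[MutationConfig, int]]:
        return sorted(self.counts.items(), key=lambda kv: (kv[0].counts(), kv[0].capped))

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (configs (k,4) int, capped (k,4) bool, counts (k,)) in stable order."""
        items = self.items_sorted()
        if not items:
            return (
                np.zeros((0, 4), dtype=np.int64),
                np.zeros((0, 4), dtype=bool),
                np.zeros(0, dtype=np.int64),
            )
        cfg = np.array([c.counts() for c, _ in items], dtype=np.int64)
        cap = np.array([c.capped for c, _ in items], dtype=bool)
        n = np.array([k for _, k in items], dtype=np.int64)
        return cfg, cap, n

    def mean_counts(self) -> np.ndarray:
        """Mean per-type count per block (capped entries enter at the sentinel value)."""
        cfg, _, n = self.as_arrays()
        if self.total == 0:
            return np.zeros(4)
        return (cfg * n[:, None]).sum(axis=0) / self.total

    # --- TSV round-trip -------------------------------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("hetA\thetB\thetAB\tfixed\tcapped_mask\tcount\n")
            for cfg, k in self.items_sorted():
                mask = "".join("1" if c else "0" for c in cfg.capped)
                fh.write(
                    f"{cfg.hetA}\t{cfg.hetB}\t{cfg.hetAB}\t{cfg.fixed}\t{mask}\t{k}\n"
                )

    @classmethod
    def from_tsv(cls, path, spec: BlockSpec | None = None) -> "BSFSTable":
        counts: dict[MutationConfig, int] = {}
        total = 0
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["hetA", "hetB", "hetAB", "fixed", "capped_mask", "count"]
            if header != expected:
                raise ValueError(f"unexpected bSFS header {header!r}")
            for line in fh:
                a, b, ab, f, mask, k = line.rstrip("\n").split("\t")
                cfg = MutationConfig(
                    int(a), int(b), int(ab), int(f),
                    tuple(ch == "1" for ch in mask),
                )
                counts[cfg] = counts.get(cfg, 0) + int(k)
                total += int(k)
        return cls(counts=counts, total=total, spec=spec or BlockSpec())


def cut_blocks(
    pair_mask: dict[str, np.ndarray], spec: BlockSpec, pair: str = ""
) -> list[Block]:
    """Cut a pair's joint callable mask into fixed-span blocks.

    ``pair_mask`` maps chromosome to a sorted (k, 2) array of 0-based
    half-open callable intervals (the intersection of the two samples'
    masks).  The walk is greedy left to right: starting from the first unused
    callable position, the next ``block_span`` callable positions form a
    candidate block; it is emitted iff its physical span does not exceed
    ``max_physical`` bp, otherwise the start advances by one callable
    position.  Blocks never share callable positions and never span
    chromosome boundaries.
    """
    blocks: list[Block] = []
    for chrom in sorted(pair_mask):
        iv = np.asarray(pair_mask[chrom], dtype=np.int64).reshape(-1, 2)
        if iv.size == 0:
            continue
        pos = np.concatenate([np.arange(s, e) for s, e in iv])
        i, n, span = 0, len(pos), spec.block_span
        while i + span <= n:
            phys = pos[i + span - 1] - pos[i] + 1
            if phys <= spec.max_physical:
                p = tuple(int(x) for x in pos[i : i + span])
                blocks.append(
                    Block(chrom=chrom, start=p[0], end=p[-1] + 1, positions=p, pair=pair)
                )
                i += span
            else:
                i += 1
    return blocks


def classify_site(gtA: tuple[int, int], gtB: tuple[int, int]) -> str:
    """Classify one biallelic site for a pair of diploids into a mutation type.

    Genotypes are unordered allele pairs of 0/1.  Returns one of
    'none', 'hetA', 'hetB', 'hetAB', 'fixed'.
    """
    if gtA is None or gtB is None or -1 in gtA or -1 in gtB:
        raise ValueError("missing genotype; pre-filter sites before classifying")
    hA = gtA[0] != gtA[1]
    hB = gtB[0] != gtB[1]
    if hA and hB:
        return "hetAB"
    if hA:
        return "hetA"
    if hB:
        return "hetB"
    if gtA[0] != gtB[0]:
        return "fixed"
    return "none"


def tally_block(
    block: Block, site_lookup: dict[int, tuple[tuple[int, int], tuple[int, int]]]
) -> MutationConfig:
    """Count mutation types over a block's callable positions.

    ``site_lookup`` maps 0-based positions (on the block's chromosome) to the
    pair's genotype tuples.  Positions without a variant record count as type
    'none'.  Variant records at non-callable positions are ignored.
    """
    c = {"hetA": 0, "hetB": 0, "hetAB": 0, "fixed": 0}
    posset = set(block.positions)
    for p in block.positions:
        gt = site_lookup.get(p)
        if gt is None:
            continue
        typ = classify_site(gt[0], gt[1])
        if typ != "none":
            c[typ] += 1
    for p in site_lookup:
        if block.start <= p < block.end and p not in posset:
            logger.debug("variant at non-callable position %d ignored", p)
    return MutationConfig(c["hetA"], c["hetB"], c["hetAB"], c["fixed"])


def apply_kmax(config: MutationConfig, kmax: int) -> MutationConfig:
    """Cap per-type counts at ``kmax``; larger counts become the sentinel kmax+1."""
    if kmax < 1:
        raise ValueError("kmax must be >= 1")
    counts = config.counts()
    capped = tuple(c > kmax for c in counts)
    new = tuple(kmax + 1 if f else c for c, f in zip(counts, capped))
    return MutationConfig(*new, capped=capped)


def aggregate_bsfs(configs: list[MutationConfig], spec: BlockSpec) -> BSFSTable:
    """Tally a list of (already capped) configurations into a bSFS table."""
    counter = Counter(configs)
    return BSFSTable(counts=dict(counter), total=len(configs), spec=spec)


def configs_from_array(counts: np.ndarray, kmax: int) -> list[MutationConfig]:
    """Convert an (n, 4) array of raw counts into capped MutationConfigs."""
    out = []
    for row in np.asarray(counts, dtype=np.int64):
        out.append(apply_kmax(MutationConfig(*[int(x) for x in row]), kmax))
    return out
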