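"""Variant, mask and outgroup-table I/O plus the site-level filtering rules.

Coordinate conventions: VCF positions are 1-based as usual; masks, BED
intervals and every internal interval computation are 0-based half-open.

The callable-site rule is per sample: a position is callable iff its depth is
at least ``min_cov`` (default 8) and at most ``mean + 0.75 * sd``, where the
moments are that sample's depth moments over all analysed positions.  Genic
and repetitive regions are removed by interval subtraction so downstream
blocks are intergenic.

Polarization against an outgroup is deliberately conservative: a site is
usable only if the outgroup shows a single allele (any site where both the
reference and alternate allele were observed counts as heterozygous
regardless of frequency) and its coverage is at least one third of the
outgroup's mean coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "VariantSite",
    "VcfData",
    "CallableMask",
    "PolarizedSite",
    "OutgroupObservation",
    "parse_vcf_biallelic",
    "build_callable_mask",
    "subtract_annotation",
    "polarize_with_outgroup",
    "merge_intervals",
    "subtract_intervals",
    "intersect_intervals",
    "read_bed",
    "write_bed",
    "read_outgroup_table",
    "write_outgroup_table",
]

# ---------------------------------------------------------------------------
# interval primitives: (k, 2) int64 arrays of sorted, non-overlapping,
# 0-based half-open intervals
# ---------------------------------------------------------------------------


def merge_intervals(iv: np.ndarray) -> np.ndarray:
    iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
    if len(iv) == 0:
        return iv
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


def subtract_intervals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """a minus b, both sorted non-overlapping half-open interval arrays."""
    a = np.asarray(a, dtype=np.int64).reshape(-1, 2)
    b = merge_intervals(b)
    if len(a) == 0 or len(b) == 0:
        return a.copy()
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return (
        np.array(out, dtype=np.int64) if out else np.zeros((0, 2), dtype=np.int64)
    )


def intersect_intervals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=np.int64).reshape(-1, 2)
    b = np.asarray(b, dtype=np.int64).reshape(-1, 2)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return (
        np.array(out, dtype=np.int64) if out else np.zeros((0, 2), dtype=np.int64)
    )


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantSite:
    """One biallelic SNP with per-sample diploid genotypes.

    ``genotypes`` is aligned with the sample order of the containing
    :class:`VcfData`; a genotype is an unordered pair of allele indices
    (0 = ref, 1 = alt) or ``None`` when missing.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: tuple[tuple[int, int] | None, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    @property
    def pos0(self) -> int:
        return self.pos - 1


@dataclass
class VcfData:
    """Parsed biallelic SNPs plus the sample -> population assignment."""

    sites: list[VariantSite]
    samples: list[str]
    populations: list[str]  # parallel to samples: 'south' | 'north' | 'outgroup'
    n_dropped: int = 0  # indel / multiallelic records


@dataclass
class CallableMask:
    """Per-sample, per-chromosome callable intervals (0-based half-open)."""

    intervals: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def samples(self) -> list[str]:
        return sorted(self.intervals)

    def get(self, sample: str, chrom: str) -> np.ndarray:
        return self.intervals.get(sample, {}).get(
            chrom, np.zeros((0, 2), dtype=np.int64)
        )

    def total_callable(self, sample: str) -> int:
        return int(
            sum(
                (iv[:, 1] - iv[:, 0]).sum()
                for iv in self.intervals.get(sample, {}).values()
            )
        )

    def pair_intersection(self, s1: str, s2: str) -> dict[str, np.ndarray]:
        """Joint callable intervals of two samples, per chromosome."""
        chroms = set(self.intervals.get(s1, {})) & set(self.intervals.get(s2, {}))
        return {
            c: intersect_intervals(self.get(s1, c), self.get(s2, c))
            for c in sorted(chroms)
        }

    def to_bed(self, path) -> None:
        """Write as a 4-column BED-like TSV (chrom, start, end, sample)."""
        with open(path, "w") as fh:
            for sample in self.samples():
                for chrom in sorted(self.intervals[sample]):
                    for s, e in self.intervals[sample][chrom]:
                        fh.write(f"{chrom}\t{s}\t{e}\t{sample}\n")

    @classmethod
    def from_bed(cls, path) -> "CallableMask":
        raw: dict[str, dict[str, list]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                chrom, s, e, sample = line.rstrip("\n").split("\t")[:4]
                raw.setdefault(sample, {}).setdefault(chrom, []).append(
                    (int(s), int(e))
                )
        mask = cls()
        for sample, by_chrom in raw.items():
            mask.intervals[sample] = {
                c: merge_intervals(np.array(v)) for c, v in by_chrom.items()
            }
        return mask


POLARIZATION_STATUSES = (
    "polarized",
    "excluded_het_outgroup",
    "excluded_low_coverage",
    "excluded_other_allele",
)


@dataclass(frozen=True)
class PolarizedSite:
    """A variant site with its inferred ancestral allele, when assignable."""

    site: VariantSite
    ancestral: str | None  # 'ref' | 'alt' | None
    status: str

    def __post_init__(self) -> None:
        if self.status not in POLARIZATION_STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if (self.status == "polarized") != (self.ancestral is not None):
            raise ValueError("ancestral must be set iff status == 'polarized'")


@dataclass(frozen=True)
class OutgroupObservation:
    """Alleles observed in the outgroup pileup at one site, with coverage."""

    chrom: str
    pos: int  # 1-based, matching the VCF
    alleles: frozenset[str]
    coverage: int


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def parse_vcf_biallelic(path, sample_map: dict[str, str]) -> VcfData:
    """Read biallelic SNPs from a VCF, dropping indels and multiallelics.

    ``sample_map`` maps sample names (all of which must be present in the
    header) to population labels.  Records are returned in file order, which
    for a valid VCF is coordinate order; genotypes of samples not in
    ``sample_map`` are ignored.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    header_samples = list(vcf.samples)
    missing = [s for s in sample_map if s not in header_samples]
    if missing:
        raise ValueError(f"samples not present in VCF header: {missing}")
    samples = [s for s in header_samples if s in sample_map]
    col = [header_samples.index(s) for s in samples]
    populations = [sample_map[s] for s in samples]

    sites: list[VariantSite] = []
    n_dropped = 0
    for rec_no, rec in enumerate(vcf, start=1):
        if not rec.is_snp or len(rec.ALT) != 1 or len(rec.REF) != 1:
            n_dropped += 1
            continue
        try:
            gts = rec.genotypes  # [a1, a2, phased] per sample
            row = []
            for c in col:
                a1, a2 = gts[c][0], gts[c][1]
                row.append(None if a1 < 0 or a2 < 0 else (int(a1), int(a2)))
            sites.append(
                VariantSite(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=rec.ALT[0],
                    genotypes=tuple(row),
                )
            )
        except Exception as exc:  # pragma: no cover - malformed record path
            raise ValueError(f"malformed VCF record #{rec_no} at {rec.CHROM}:{rec.POS}: {exc}")
    logger.info("parsed %d biallelic SNPs, dropped %d records", len(sites), n_dropped)
    return VcfData(
        sites=sites, samples=samples, populations=populations, n_dropped=n_dropped
    )


def build_callable_mask(
    depths: dict[str, dict[str, np.ndarray]],
    min_cov: int = 8,
    sd_mult: float = 0.75,
) -> CallableMask:
    """Derive per-sample callable intervals from per-position depth tracks.

    ``depths`` maps sample -> chrom -> integer depth array indexed from
    position 0.  A position is callable iff
    ``min_cov <= depth <= mean + sd_mult * sd`` with the moments taken per
    sample over all positions of all chromosomes (population sd, ddof=0).
    Both bounds are inclusive.
    """
    mask = CallableMask()
    for sample, by_chrom in depths.items():
        if not by_chrom or all(len(np.ravel(d)) == 0 for d in by_chrom.values()):
            raise ValueError(f"empty depth track for sample {sample!r}")
        allv = np.concatenate([np.ravel(d) for d in by_chrom.values()]).astype(float)
        if (allv < 0).any():
            raise ValueError("depths must be non-negative")
        mean, sd = allv.mean(), allv.std(ddof=0)
        cap = mean + sd_mult * sd
        mask.intervals[sample] = {}
        for chrom, d in by_chrom.items():
            d = np.ravel(np.asarray(d))
            ok = (d >= min_cov) & (d <= cap)
            mask.intervals[sample][chrom] = _bool_to_intervals(ok)
    return mask


def _bool_to_intervals(ok: np.ndarray) -> np.ndarray:
    if len(ok) == 0 or not ok.any():
        return np.zeros((0, 2), dtype=np.int64)
    diff = np.diff(ok.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1) + 1
    if ok[0]:
        starts = np.r_[0, starts]
    if ok[-1]:
        ends = np.r_[ends, len(ok)]
    return np.stack([starts, ends], axis=1).astype(np.int64)


def subtract_annotation(
    mask: CallableMask, exclude: dict[str, np.ndarray]
) -> CallableMask:
    """Remove annotated (e.g. genic/repeat) intervals from every sample's mask."""
    cleaned: dict[str, np.ndarray] = {}
    for chrom, iv in exclude.items():
        iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
        if len(iv) > 1 and (np.diff(iv[:, 0]) < 0).any():
            logger.warning("exclusion BED for %s is unsorted; sorting", chrom)
        cleaned[chrom] = merge_intervals(iv)
    out = CallableMask()
    for sample, by_chrom in mask.intervals.items():
        out.intervals[sample] = {
            chrom: subtract_intervals(iv, cleaned.get(chrom, np.zeros((0, 2))))
            for chrom, iv in by_chrom.items()
        }
    return out


def polarize_with_outgroup(
    sites: list[VariantSite],
    outgroup: dict[tuple[str, int], OutgroupObservation],
    mean_cov: float,
) -> list[PolarizedSite]:
    """Assign ancestral alleles from outgroup pileup observations.

    A site is excluded when outgroup coverage is below ``mean_cov / 3``, when
    the outgroup shows both the ref and the alt allele (heterozygous by the
    conservative rule), or when it shows an allele that is neither.  The
    output has exactly one entry per input site.
    """
    if mean_cov <= 0:
        raise ValueError("mean_cov must be > 0")
    out: list[PolarizedSite] = []
    threshold = mean_cov / 3.0
    for site in sites:
        obs = outgroup.get((site.chrom, site.pos))
        if obs is None or obs.coverage < threshold:
            out.append(PolarizedSite(site, None, "excluded_low_coverage"))
            continue
        alleles = set(obs.alleles)
        if site.ref in alleles and site.alt in alleles:
            out.append(PolarizedSite(site, None, "excluded_het_outgroup"))
        elif alleles == {site.ref}:
            out.append(PolarizedSite(site, "ref", "polarized"))
        elif alleles == {site.alt}:
            out.append(PolarizedSite(site, "alt", "polarized"))
        else:
            out.append(PolarizedSite(site, None, "excluded_other_allele"))
    return out


# ---------------------------------------------------------------------------
# plain-text readers/writers
# ---------------------------------------------------------------------------


def read_bed(path) -> dict[str, np.ndarray]:
    """Read a 3+ column BED into per-chromosome merged interval arrays."""
    raw: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            raw.setdefault(f[0], []).append((int(f[1]), int(f[2])))
    return {c: merge_intervals(np.array(v)) for c, v in sorted(raw.items())}


def write_bed(intervals: dict[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for s, e in intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def read_outgroup_table(path) -> dict[tuple[str, int], OutgroupObservation]:
    """Read the outgroup pileup table (chrom, pos, alleles_observed, coverage)."""
    out: dict[tuple[str, int], OutgroupObservation] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["chrom", "pos", "alleles_observed", "coverage"]:
            raise ValueError(f"unexpected outgroup table header {header!r}")
        for line in fh:
            chrom, pos, alleles, cov = line.rstrip("\n").split("\t")
            obs = OutgroupObservation(
                chrom=chrom,
                pos=int(pos),
                alleles=frozenset(alleles.split(",")) if alleles else frozenset(),
                coverage=int(cov),
            )
            out[(obs.chrom, obs.pos)] = obs
    return out


def write_outgroup_table(
    observations: list[OutgroupObservation] | dict, path
) -> None:
    if isinstance(observations, dict):
        observations = list(observations.values())
    observations = sorted(observations, key=lambda o: (o.chrom, o.pos))
    with open(path, "w") as fh:
        fh.write("chrom\tpos\talleles_observed\tcoverage\n")
        for o in observations:
            alleles = ",".join(sorted(o.alleles))
            fh.write(f"{o.chrom}\t{o.pos}\t{alleles}\t{o.coverage}\n")
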