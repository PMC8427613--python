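"""Segment-table containers and SEG-like TSV input/output.

Files use 1-based closed intervals (the SEG convention); in memory all
coordinates are 0-based half-open. The ``log2ratio`` dialect converts a
segment mean value v to absolute copy number ``ploidy_hint * 2**v``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import AUTOSOMES, GenomeBuild

logger = logging.getLogger(__name__)

SEG_COLUMNS = ["sample", "chrom", "start", "end", "num_probes", "cn"]


@dataclass
class Segment:
    chrom: str
    start: int  # 0-based, half-open
    end: int
    cn: float
    n_probes: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentProfile:
    """One sample's absolute copy-number segments on a genome build."""

    sample_id: str
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sort()

    def sort(self) -> None:
        self.segments.sort(key=lambda s: (AUTOSOMES.index(s.chrom), s.start))

    def by_chromosome(self) -> dict[str, list[Segment]]:
        out: dict[str, list[Segment]] = {}
        for seg in self.segments:
            out.setdefault(seg.chrom, []).append(seg)
        return out

    def validate(self, genome: GenomeBuild | None = None) -> None:
        for chrom, segs in self.by_chromosome().items():
            prev_end = -1
            for seg in segs:
                if seg.start >= seg.end:
                    raise ValueError(
                        f"sample {self.sample_id}: empty segment "
                        f"{chrom}:{seg.start}-{seg.end}"
                    )
                if seg.cn < 0:
                    raise ValueError(
                        f"sample {self.sample_id}: negative copy number {seg.cn} "
                        f"at {chrom}:{seg.start}-{seg.end}"
                    )
                if seg.start < prev_end:
                    raise ValueError(
                        f"sample {self.sample_id}: overlapping segments on chromosome "
                        f"{chrom} at {seg.start}-{seg.end}"
                    )
                if genome is not None and seg.end > genome.lengths[chrom]:
                    raise ValueError(
                        f"sample {self.sample_id}: segment {chrom}:{seg.start}-{seg.end} "
                        f"exceeds chromosome length {genome.lengths[chrom]}"
                    )
                prev_end = seg.end

    def total_length(self) -> int:
        return sum(s.length for s in self.segments)


def read_seg(
    path,
    genome: GenomeBuild | None = None,
    dialect: str = "abs_cn",
    ploidy_hint: float = 2.0,
) -> list[SegmentProfile]:
    """Read a SEG-like tab-delimited table into per-sample profiles.

    Expected columns: sample, chrom, start, end, [num_probes], cn.
    Chromosomes outside 1..22 are dropped (count logged). With
    ``dialect="log2ratio"`` the value column holds log2 segment means and
    is rescaled to absolute CN against ``ploidy_hint``.
    """
    if dialect not in ("abs_cn", "log2ratio"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    required = {"sample", "chrom", "start", "end", "cn"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")

    non_autosomal = ~df["chrom"].isin(AUTOSOMES)
    if non_autosomal.any():
        logger.info(
            "read_seg: dropped %d rows on non-autosomal chromosomes (%s)",
            int(non_autosomal.sum()),
            ", ".join(sorted(df.loc[non_autosomal, "chrom"].unique())),
        )
        df = df[~non_autosomal]

    has_probes = "num_probes" in df.columns
    profiles = []
    for sample_id, sub in df.groupby("sample", sort=True):
        segs = []
        for row in sub.itertuples(index=False):
            value = float(row.cn)
            cn = ploidy_hint * 2.0**value if dialect == "log2ratio" else value
            if cn < 0:
                raise ValueError(
                    f"sample {sample_id}: negative copy number {cn} at "
                    f"{row.chrom}:{row.start}-{row.end}"
                )
            n_probes = None
            if has_probes and not pd.isna(row.num_probes):
                n_probes = int(row.num_probes)
            segs.append(
                Segment(
                    chrom=str(row.chrom),
                    start=int(row.start) - 1,  # 1-based closed -> 0-based half-open
                    end=int(row.end),
                    cn=cn,
                    n_probes=n_probes,
                )
            )
        profile = SegmentProfile(sample_id=str(sample_id), segments=segs)
        profile.validate(genome)
        profiles.append(profile)
    return profiles


def write_seg(profiles: list[SegmentProfile], path) -> None:
    """Write profiles as a SEG-like TSV; round-trips with :func:`read_seg`."""
    rows = []
    for p in profiles:
        for s in p.segments:
            rows.append(
                {
                    "sample": p.sample_id,
                    "chrom": s.chrom,
                    "start": s.start + 1,
                    "end": s.end,
                    "num_probes": s.n_probes,
                    "cn": round(float(s.cn), 6),
                }
            )
    df = pd.DataFrame(rows, columns=SEG_COLUMNS)
    if df["num_probes"].isna().all():
        df = df.drop(columns=["num_probes"])
    else:
        df["num_probes"] = df["num_probes"].astype("Int64")
    df.to_csv(path, sep="\t", index=False)


def filter_min_probes(profile: SegmentProfile, min_probes: int = 5) -> SegmentProfile:
    """Drop segments supported by fewer than ``min_probes`` probes.

    Mirrors the array-platform QC step used when projecting signatures onto
    SNP-array segment tables: segments under the probe-support threshold are
    removed outright, with no re-bridging of the resulting gaps.
    """
    if any(s.n_probes is None for s in profile.segments):
        raise ValueError(
            f"sample {profile.sample_id}: n_probes missing on some segments; "
            "skip the probe filter for this profile"
        )
    kept = [s for s in profile.segments if s.n_probes >= min_probes]
    if not kept and profile.segments:
        warnings.warn(
            f"sample {profile.sample_id}: all segments below {min_probes} probes; "
            "profile is now empty",
            stacklevel=2,
        )
    return SegmentProfile(sample_id=profile.sample_id, segments=kept)


@dataclass
class BinnedCounts:
    """Read counts over an ordered genomic bin set, bins x samples."""

    bins: pd.DataFrame  # columns chrom, start, end (0-based half-open)
    counts: pd.DataFrame  # index aligned with bins rows, one column per sample

    def __post_init__(self) -> None:
        if len(self.bins) != len(self.counts):
            raise ValueError("bins and counts row counts differ")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("sample with zero total count")
        for chrom, sub in self.bins.groupby("chrom", sort=False):
            if not (sub["start"].values[1:] >= sub["end"].values[:-1]).all():
                raise ValueError(f"bins overlap or are unsorted on chromosome {chrom}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def read_bins(path) -> pd.DataFrame:
    """Read a BED-like TSV bin set (chrom, start, end; 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return df[["chrom", "start", "end"]]


def make_uniform_bins(genome: GenomeBuild, bin_size: int) -> pd.DataFrame:
    """Tile each autosome with fixed-width bins (last bin truncated)."""
    rows = []
    for chrom in genome.chromosomes:
        length = genome.lengths[chrom]
        starts = np.arange(0, length, bin_size)
        for s in starts:
            rows.append({"chrom": chrom, "start": int(s), "end": int(min(s + bin_size, length))})
    return pd.DataFrame(rows)


def read_counts(counts_path, bins_path) -> BinnedCounts:
    bins = read_bins(bins_path)
    counts = pd.read_csv(counts_path, sep="\t")
    return BinnedCounts(bins=bins, counts=counts)


def write_counts(bc: BinnedCounts, counts_path, bins_path) -> None:
    bc.bins.to_csv(bins_path, sep="\t", index=False)
    bc.counts.to_csv(counts_path, sep="\t", index=False)
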