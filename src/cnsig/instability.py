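"""Genome-instability summaries: sample ploidy and the wGII score.

wGII (weighted genome integrity/instability index) is the mean over the 22
autosomes of the fraction of each chromosome's covered length whose copy
number deviates from the sample's ploidy. Averaging per-chromosome
fractions removes the bias large chromosomes would otherwise carry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import round_half_up
from .genome import GenomeBuild
from .segments import SegmentProfile

__all__ = ["InstabilityScores", "sample_ploidy", "wgii", "wgii_cohort"]


@dataclass
class InstabilityScores:
    sample_id: str
    ploidy: int
    wgii: float
    chromosome_fractions: dict[str, float]


def sample_ploidy(profile: SegmentProfile) -> int:
    """Length-weighted mean CN rounded half-up, floored at 1."""
    if not profile.segments:
        raise ValueError(f"sample {profile.sample_id}: empty profile")
    lengths = np.array([s.length for s in profile.segments], dtype=float)
    cns = np.array([s.cn for s in profile.segments], dtype=float)
    mean_cn = float((lengths * cns).sum() / lengths.sum())
    return max(int(round_half_up(mean_cn)), 1)


def wgii(
    profile: SegmentProfile,
    genome: GenomeBuild,
    mode: str = "rounded",
    threshold: float = 0.5,
) -> InstabilityScores:
    """Per-chromosome altered fraction and their mean across the autosomes.

    A basepair counts as altered when its segment's rounded CN differs from
    the (integer) sample ploidy; ``mode="threshold"`` instead calls
    |cn - ploidy| > ``threshold``. Genome not covered by any segment is
    excluded from numerator and denominator; chromosomes with no coverage
    are excluded from the average with a warning.
    """
    ploidy = sample_ploidy(profile)
    by_chrom = profile.by_chromosome()
    fractions: dict[str, float] = {}
    for chrom in genome.chromosomes:
        segs = by_chrom.get(chrom)
        if not segs:
            continue
        covered = altered = 0
        for s in segs:
            covered += s.length
            if mode == "rounded":
                is_altered = int(round_half_up(s.cn)) != ploidy
            elif mode == "threshold":
                is_altered = abs(s.cn - ploidy) > threshold
            else:
                raise ValueError(f"unknown mode {mode!r}")
            if is_altered:
                altered += s.length
        fractions[chrom] = altered / covered
    if len(fractions) < len(genome.chromosomes):
        missing = sorted(set(genome.chromosomes) - set(fractions), key=int)
        warnings.warn(
            f"sample {profile.sample_id}: no coverage on chromosomes {missing}; "
            "excluded from the wGII average",
            stacklevel=2,
        )
    score = float(np.mean(list(fractions.values())))
    return InstabilityScores(
        sample_id=profile.sample_id, ploidy=ploidy, wgii=score,
        chromosome_fractions=fractions,
    )


def wgii_cohort(profiles: list[SegmentProfile], genome: GenomeBuild,
                **kwargs) -> pd.DataFrame:
    """wGII table for a cohort: sample, ploidy, wgii, per-chromosome fractions."""
    rows = []
    for p in profiles:
        s = wgii(p, genome, **kwargs)
        row = {"sample": s.sample_id, "ploidy": s.ploidy, "wgii": s.wgii}
        for chrom in genome.chromosomes:
            row[f"frac_chr{chrom}"] = s.chromosome_fractions.get(chrom, np.nan)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")
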