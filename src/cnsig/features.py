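"""The six fundamental copy-number features.

Each sample's segment profile is summarized as event multisets for:

- ``segsize``     segment length in bp (one event per segment)
- ``copynumber``  absolute CN of each segment
- ``changepoint`` |CN difference| between adjacent segments on a chromosome
- ``bp10MB``      breakpoint count in non-overlapping 10 Mb tiles
- ``bpchrarm``    breakpoint count per chromosome arm (p and q)
- ``osCN``        lengths of maximal chains (>= 3 segments) whose rounded CN
                  oscillates between exactly two integer states

A breakpoint is the internal boundary between two adjacent segments of a
chromosome. Zero-count tiles/arms are kept as events so quiet genomes
contribute mass to the count-feature mixtures; chromosomes without an
oscillating chain emit a single 0-length osCN event.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeBuild
from .segments import SegmentProfile

FEATURE_NAMES = ("segsize", "copynumber", "changepoint", "bp10MB", "bpchrarm", "osCN")
CONTINUOUS_FEATURES = ("segsize", "copynumber", "changepoint")
COUNT_FEATURES = ("bp10MB", "bpchrarm", "osCN")

TILE_BP = 10_000_000


def round_half_up(x) -> np.ndarray:
    """Round to nearest integer with halves going up (2.5 -> 3)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass
class FeatureEvents:
    """Per-sample event multisets for the six CN features."""

    sample_id: str
    events: dict[str, list[float]] = field(default_factory=dict)

    def __getitem__(self, feature: str) -> list[float]:
        return self.events[feature]

    def total_breakpoints(self) -> int:
        return int(sum(self.events["bpchrarm"]))


def extract_features(
    profile: SegmentProfile,
    genome: GenomeBuild,
    include_zero_events: bool = True,
    partial_tiles: bool = True,
) -> FeatureEvents:
    """Compute the six feature event multisets for one sample."""
    ev: dict[str, list[float]] = {name: [] for name in FEATURE_NAMES}
    by_chrom = profile.by_chromosome()

    for chrom in genome.chromosomes:
        segs = by_chrom.get(chrom, [])
        cns = np.array([s.cn for s in segs])

        ev["segsize"].extend(float(s.length) for s in segs)
        ev["copynumber"].extend(float(c) for c in cns)
        if len(segs) > 1:
            ev["changepoint"].extend(np.abs(np.diff(cns)).tolist())

        # internal boundaries between adjacent segments
        breakpoints = [segs[i].end for i in range(len(segs) - 1)]

        length = genome.lengths[chrom]
        n_full, rem = divmod(length, TILE_BP)
        n_tiles = n_full + (1 if (rem and partial_tiles) else 0)
        tile_counts = np.zeros(max(n_tiles, 1), dtype=int)
        for bp in breakpoints:
            t = min(bp // TILE_BP, len(tile_counts) - 1)
            tile_counts[t] += 1
        if include_zero_events:
            ev["bp10MB"].extend(float(c) for c in tile_counts)
        else:
            ev["bp10MB"].extend(float(c) for c in tile_counts if c > 0)

        p_count = sum(1 for bp in breakpoints if genome.arm(chrom, bp) == "p")
        q_count = len(breakpoints) - p_count
        for c in (p_count, q_count):
            if include_zero_events or c > 0:
                ev["bpchrarm"].append(float(c))

        chains = oscillating_chains(cns)
        if chains:
            ev["osCN"].extend(float(c) for c in chains)
        elif include_zero_events:
            ev["osCN"].append(0.0)

    return FeatureEvents(sample_id=profile.sample_id, events=ev)


def oscillating_chains(cns: np.ndarray) -> list[int]:
    """Lengths of maximal runs of >=3 segments alternating between exactly
    two distinct rounded-integer CN states."""
    if len(cns) < 3:
        return []
    states = round_half_up(cns).astype(int)
    chains = []
    start = 0
    while start < len(states) - 2:
        if states[start + 1] == states[start]:
            start += 1
            continue
        a, b = states[start], states[start + 1]
        end = start + 2
        while end < len(states) and states[end] == (a if (end - start) % 2 == 0 else b):
            end += 1
        if end - start >= 3:
            chains.append(end - start)
            start = end - 1  # last segment can seed a new alternation pair
        else:
            start += 1
    return chains


def extract_cohort(
    profiles: list[SegmentProfile], genome: GenomeBuild, **kwargs
) -> list[FeatureEvents]:
    return [extract_features(p, genome, **kwargs) for p in profiles]


def pooled_values(cohort: list[FeatureEvents], feature: str) -> np.ndarray:
    """All samples' events for one feature pooled into a single array."""
    arrays = [np.asarray(fe.events[feature], dtype=float) for fe in cohort]
    arrays = [a for a in arrays if a.size]
    return np.concatenate(arrays) if arrays else np.array([])


def save_events(cohort: list[FeatureEvents], path) -> None:
    doc = {fe.sample_id: {f: list(map(float, fe.events[f])) for f in FEATURE_NAMES} for fe in cohort}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_events(path) -> list[FeatureEvents]:
    with open(path) as fh:
        doc = json.load(fh)
    return [FeatureEvents(sample_id=s, events={f: list(v[f]) for f in FEATURE_NAMES})
            for s, v in doc.items()]
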