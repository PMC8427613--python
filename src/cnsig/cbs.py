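"""Circular binary segmentation of binned read counts.

Recursive change-point detection: within each candidate segment the arc
(i, j) maximizing the two-sample t-statistic between the arc and its
complement is found by exhaustive scan; the split is accepted when its
within-segment permutation p-value falls below ``alpha``. Segment copy
number is anchored to a diploid baseline: cn = 2 * 2**(mean log2 ratio).
"""

from __future__ import annotations

import hashlib

import numpy as np

from .genome import GenomeBuild
from .segments import BinnedCounts, Segment, SegmentProfile

__all__ = ["cbs_segment", "max_t_arc"]


def _sample_seed(run_seed: int, sample_id: str) -> int:
    digest = hashlib.sha256(f"{run_seed}:{sample_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def max_t_arc(x: np.ndarray, min_width: int = 2) -> tuple[int, int, float]:
    """Exhaustive scan for the arc [i, j) maximizing |t| vs its complement.

    Both the arc and its complement must contain at least ``min_width``
    bins. Ties break toward smallest i, then smallest j. Returns
    (i, j, |t|); (|t| = 0 when no admissible arc exists).
    """
    n = len(x)
    if n < 2 * min_width:
        return 0, n, 0.0
    s = np.concatenate([[0.0], np.cumsum(x)])
    ss = np.concatenate([[0.0], np.cumsum(x * x)])
    total, total_sq = s[-1], ss[-1]

    i_idx = np.arange(n + 1)
    # arc sums for all (i, j), j > i: broadcast as matrices
    arc_sum = s[None, :] - s[:, None]  # [i, j]
    arc_len = i_idx[None, :] - i_idx[:, None]
    arc_sq = ss[None, :] - ss[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        comp_len = n - arc_len
        mean_a = arc_sum / arc_len
        mean_c = (total - arc_sum) / comp_len
        rss = (arc_sq - arc_len * mean_a**2) + (
            (total_sq - arc_sq) - comp_len * mean_c**2
        )
        pooled = rss / max(n - 2, 1)
        denom = np.sqrt(pooled * (1.0 / arc_len + 1.0 / comp_len))
        t = np.abs(mean_a - mean_c) / denom
    t = np.where(np.isfinite(t), t, np.where(np.abs(mean_a - mean_c) > 0, np.inf, 0.0))
    valid = (arc_len >= min_width) & (comp_len >= min_width)
    t = np.where(valid, t, -1.0)
    best_flat = int(np.argmax(t))  # row-major: smallest i first, then smallest j
    i, j = divmod(best_flat, n + 1)
    return i, j, float(max(t[i, j], 0.0))


def _perm_pvalue(x: np.ndarray, t_obs: float, min_width: int, n_perm: int, rng) -> float:
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(x)
        _, _, t_p = max_t_arc(perm, min_width)
        if t_p >= t_obs:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


def _segment_array(
    x: np.ndarray, alpha: float, min_width: int, n_perm: int, rng
) -> list[tuple[int, int]]:
    """Recursive CBS on one chromosome's log-ratio vector -> bin intervals."""
    out: list[tuple[int, int]] = []
    stack = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        seg = x[lo:hi]
        if hi - lo < 2 * min_width:
            out.append((lo, hi))
            continue
        i, j, t_obs = max_t_arc(seg, min_width)
        if t_obs <= 0:
            out.append((lo, hi))
            continue
        p = _perm_pvalue(seg, t_obs, min_width, n_perm, rng)
        if p >= alpha:
            out.append((lo, hi))
            continue
        cuts = sorted({0, i, j, hi - lo})
        for a, b in zip(cuts[:-1], cuts[1:]):
            stack.append((lo + a, lo + b))
    return sorted(out)


def cbs_segment(
    counts: BinnedCounts,
    genome: GenomeBuild,
    alpha: float = 0.01,
    min_width: int = 2,
    n_perm: int = 200,
    seed: int = 0,
    merge_tol: float = 0.3,
    ploidy_hint: float = 2.0,
) -> list[SegmentProfile]:
    """Segment per-sample binned counts into absolute-CN segment profiles.

    Counts are normalized per sample to per-bin ratios (count / sample mean
    count), log2-transformed with a 0.5 pseudocount, and segmented per
    chromosome. Adjacent output segments whose CN differs by less than
    ``merge_tol`` are merged (a pragmatic stand-in for array-style
    false-positive breakpoint pruning).
    """
    profiles = []
    bins = counts.bins.reset_index(drop=True)
    for sample_id in counts.samples:
        rng = np.random.default_rng(_sample_seed(seed, sample_id))
        c = counts.counts[sample_id].to_numpy(dtype=float)
        mean = c.mean()
        logratio = np.log2((c + 0.5) / (mean + 0.5))
        segs: list[Segment] = []
        for chrom, sub in bins.groupby("chrom", sort=False):
            idx = sub.index.to_numpy()
            x = logratio[idx]
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if len(x) < min_width:
                intervals = [(0, len(x))]
            else:
                intervals = _segment_array(x, alpha, min_width, n_perm, rng)
            for lo, hi in intervals:
                cn = ploidy_hint * 2.0 ** float(x[lo:hi].mean())
                segs.append(
                    Segment(
                        chrom=str(chrom),
                        start=int(starts[lo]),
                        end=int(ends[hi - 1]),
                        cn=cn,
                        n_probes=hi - lo,
                    )
                )
        segs = _merge_adjacent(segs, merge_tol)
        profiles.append(SegmentProfile(sample_id=sample_id, segments=segs))
    return profiles


def _merge_adjacent(segs: list[Segment], merge_tol: float) -> list[Segment]:
    merged: list[Segment] = []
    for seg in segs:
        if (
            merged
            and merged[-1].chrom == seg.chrom
            and merged[-1].end == seg.start
            and abs(merged[-1].cn - seg.cn) < merge_tol
        ):
            prev = merged[-1]
            w_prev = prev.n_probes or prev.length
            w_cur = seg.n_probes or seg.length
            cn = (prev.cn * w_prev + seg.cn * w_cur) / (w_prev + w_cur)
            merged[-1] = Segment(
                chrom=prev.chrom,
                start=prev.start,
                end=seg.end,
                cn=cn,
                n_probes=(prev.n_probes or 0) + (seg.n_probes or 0) or None,
            )
        else:
            merged.append(seg)
    return merged
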