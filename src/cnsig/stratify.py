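"""Prognostic subgroup assignment and cross-cohort signature projection.

Three subgroups: quiet genomes (wGII below a cutoff, default 0.1) form
"wGIIlow"; the remaining samples are halved around their instability-
signature (Sig6) exposure into "Sig6high" / "Sig6low". For external
cohorts encoded with the frozen reference component model, samples are
scored by Spearman correlation of their component vector with the
reference Sig6 definition, the lowest-correlated third dropped, and the
survivors bisected at the median correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

WGII_LOW = "wGIIlow"
SIG6_LOW = "Sig6low"
SIG6_HIGH = "Sig6high"

__all__ = ["classify_cohort", "project_by_correlation", "Classification",
           "WGII_LOW", "SIG6_LOW", "SIG6_HIGH"]


@dataclass
class Classification:
    labels: pd.Series  # sample -> label
    realized_split: float  # the Sig6 cutoff actually applied
    wgii_cutoff: float
    scores: pd.Series | None = None  # correlation scores (projection mode)
    dropped: list[str] | None = None
    realized_drop_cutoff: float | None = None


def classify_cohort(
    sig6_exposure: pd.Series,
    wgii_scores: pd.Series,
    wgii_cutoff: float = 0.1,
    sig6_split: float | None = None,
) -> Classification:
    """Assign wGIIlow / Sig6low / Sig6high subgroup labels.

    Samples with wGII below ``wgii_cutoff`` are wGIIlow; the rest are split
    at the median Sig6 exposure (ties to high) unless a fixed numeric
    ``sig6_split`` is supplied (the frozen-threshold path for classifying
    new single samples). Samples missing a wGII value are excluded with a
    warning.
    """
    missing = [s for s in sig6_exposure.index if s not in wgii_scores.index
               or pd.isna(wgii_scores.get(s))]
    if missing:
        logger.warning("classify_cohort: excluding samples without wGII: %s", missing)
    samples = [s for s in sig6_exposure.index if s not in missing]

    labels = {}
    rest = []
    for s in samples:
        if wgii_scores[s] < wgii_cutoff:
            labels[s] = WGII_LOW
        else:
            rest.append(s)
    if sig6_split is None:
        split = float(np.median(sig6_exposure[rest])) if rest else math.nan
    else:
        split = float(sig6_split)
    for s in rest:
        labels[s] = SIG6_HIGH if sig6_exposure[s] >= split else SIG6_LOW
    return Classification(
        labels=pd.Series(labels, name="subgroup").reindex(samples),
        realized_split=split,
        wgii_cutoff=wgii_cutoff,
    )


def project_by_correlation(
    M_ext: pd.DataFrame,
    w_sig6: pd.Series,
    drop_fraction: float = 1.0 / 3.0,
) -> Classification:
    """Project the reference instability signature onto an external cohort.

    Each sample's component vector is Spearman-correlated (average ranks)
    with the reference Sig6 definition; the lowest ``drop_fraction`` of
    samples is removed — exactly ``ceil((1 - drop_fraction) * n)`` are
    retained, breaking ties at the boundary by keeping strictly greater
    correlations first and filling the remaining quota in sample-id order —
    and the survivors are bisected at their median correlation (ties to
    high). Constant component vectors have undefined correlation and are
    dropped with a warning.
    """
    if list(M_ext.columns) != list(w_sig6.index):
        raise ValueError("component labels do not match the reference signature")
    w = w_sig6.to_numpy(dtype=float)

    corrs = {}
    undefined = []
    for sample, row in M_ext.iterrows():
        v = row.to_numpy(dtype=float)
        if np.allclose(v, v[0]):
            undefined.append(sample)
            continue
        rho = spearmanr(v, w).statistic
        corrs[sample] = float(rho)
    if undefined:
        logger.warning("project_by_correlation: constant component vectors "
                       "(correlation undefined), dropped: %s", undefined)
    scores = pd.Series(corrs, name="sig6_correlation")

    n = len(scores)
    # epsilon guards the exact-fraction case ((1 - 1/3) * 9 -> 6, not 7)
    n_keep = math.ceil((1.0 - drop_fraction) * n - 1e-9)
    ordered = scores.sort_values(ascending=False)
    if n_keep <= 0:
        kept_ids: list = []
        boundary = math.nan
    else:
        boundary = float(ordered.iloc[n_keep - 1])
        above = ordered[ordered > boundary].index.tolist()
        at = sorted(ordered[ordered == boundary].index)
        kept_ids = above + at[: n_keep - len(above)]
    dropped = undefined + [s for s in scores.index if s not in kept_ids]

    kept = scores[kept_ids]
    split = float(kept.median()) if len(kept) else math.nan
    labels = pd.Series(
        {s: (SIG6_HIGH if kept[s] >= split else SIG6_LOW) for s in kept_ids},
        name="subgroup",
    )
    return Classification(
        labels=labels,
        realized_split=split,
        wgii_cutoff=math.nan,
        scores=scores,
        dropped=dropped,
        realized_drop_cutoff=float(kept.min()) if len(kept) else math.nan,
    )
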