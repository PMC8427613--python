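"""Study-scale benchmark routines.

Each function runs one validation scenario from scratch at the package's
reference problem sizes — cohort-description arithmetic, mixture/signature
parameter recovery on simulated cohorts, survival-model calibration, and
the end-to-end subgroup-prognosis recovery — and returns summary numbers.
They are consumed by the acceptance test suite and the reproduction
script; all randomness derives from the ``seed`` argument.
"""

from __future__ import annotations

import os
import tempfile

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr

from .cohort import muscle_invasive_count, proportion_pct, REFERENCE_COHORT_COUNTS
from .features import extract_cohort
from .mixtures import FeatureMixtureModel, fit_mixture
from .pipeline import RunConfig, run_pipeline
from .segments import write_seg
from .signatures import CNSignatureModel, match_signatures
from .simulate import (
    GenerativeConfig,
    generate_cohort,
    simulate_survival_cohort,
    true_signature_definitions,
)
from .survival import cox_fit, km_logrank


def _sub_seed(seed: int, i: int) -> int:
    return (seed * 100_003 + i * 7919) % (2**31 - 1)


def table1_proportions() -> dict[str, float]:
    """Cohort-description percentages recomputed from the reference counts."""
    c = REFERENCE_COHORT_COUNTS
    return {
        "female_pct": proportion_pct(c["gender_female"]),
        "smoking_pct": proportion_pct(c["smoking"]),
        "aa_intake_pct": proportion_pct(c["aa_intake"]),
        "muscle_invasive_pct": proportion_pct(muscle_invasive_count()),
        "metastasis_pct": proportion_pct(c["metastasis"]),
        "progression_pct": proportion_pct(c["cancer_progression"]),
    }


def mixture_recovery(seed: int = 0, n_seeds: int = 20, n: int = 2000) -> dict:
    """Component-count and parameter recovery on simulated mixtures.

    Poisson: 50/50 mix of rates 1 and 10 (recovered rates must fall in
    [0.8, 1.2] and [9, 11]); Gaussian: means 0.5/3.0 with sd 0.2 (means
    within +-0.1). Returns the fraction of seeds fully recovered per family.
    """
    pois_ok = gauss_ok = 0
    for i in range(n_seeds):
        rng = np.random.default_rng(_sub_seed(seed, i))
        x = np.concatenate([rng.poisson(1, n // 2), rng.poisson(10, n // 2)])
        m = fit_mixture(x, "poisson", k_range=range(1, 6), n_init=4,
                        seed=_sub_seed(seed, i))
        if m.k == 2 and 0.8 <= m.params[0, 0] <= 1.2 and 9 <= m.params[1, 0] <= 11:
            pois_ok += 1
        y = np.concatenate([rng.normal(0.5, 0.2, n // 2), rng.normal(3.0, 0.2, n // 2)])
        g = fit_mixture(y, "gaussian", k_range=range(1, 6), n_init=4,
                        seed=_sub_seed(seed, 1000 + i))
        if g.k == 2 and abs(g.params[0, 0] - 0.5) <= 0.1 and abs(g.params[1, 0] - 3.0) <= 0.1:
            gauss_ok += 1
    return {
        "poisson_recovery_frac": pois_ok / n_seeds,
        "gaussian_recovery_frac": gauss_ok / n_seeds,
        "n_seeds": n_seeds,
    }


def signature_recovery(seed: int = 0, n_seeds: int = 20, n_samples: int = 200) -> dict:
    """Rank, definition and exposure recovery on K=3 synthetic cohorts."""
    rank_hits = 0
    cosines = []
    pearsons = []
    for i in range(n_seeds):
        s = _sub_seed(seed, i)
        cfg = GenerativeConfig(n_samples=n_samples, seed=s, quiet_fraction=0.0)
        profiles, _, truth = generate_cohort(cfg)
        events = extract_cohort(profiles, cfg.genome)
        mix = FeatureMixtureModel(events).fit(k_range=range(1, 7), n_init=3, seed=s)
        model = CNSignatureModel(mix.matrix)
        diag = model.select_rank(k_range=range(2, 6), n_runs=6, seed=s)
        rank_hits += diag.recommended_k == cfg.K
        fit = model.fit(k=cfg.K, n_runs=15, seed=s)
        w_true = true_signature_definitions(cfg, mix.model, n_per_signature=25, seed=s)
        cosines.append(float(match_signatures(fit.W, w_true)["cosine"].mean()))
        corr = np.zeros((cfg.K, cfg.K))
        for a, name in enumerate(truth.exposures.columns):
            for b, col in enumerate(fit.exposures.columns):
                corr[a, b] = pearsonr(truth.exposures[name], fit.exposures[col]).statistic
        ri, cj = linear_sum_assignment(-corr)
        pearsons.append(float(corr[ri, cj].mean()))
    return {
        "rank_recovery_frac": rank_hits / n_seeds,
        "mean_matched_cosine": float(np.mean(cosines)),
        "mean_exposure_pearson": float(np.mean(pearsons)),
        "n_seeds": n_seeds,
    }


def survival_recovery(seed: int = 0, n_seeds: int = 20, n: int = 300,
                      hr: float = 3.2, censoring: float = 0.3) -> dict:
    """Cox CI coverage of the true subgroup hazard ratio."""
    covered = 0
    hrs = []
    for i in range(n_seeds):
        df = simulate_survival_cohort(n=n, hr=hr, censoring_rate=censoring,
                                      seed=_sub_seed(seed, i)).astype({"group": float})
        res = cox_fit(df, ["group"], "time", "event")
        lo, hi = res.table.loc["group", ["ci_low", "ci_high"]]
        covered += lo <= hr <= hi
        hrs.append(float(res.table.loc["group", "hr"]))
    return {
        "ci_coverage_frac": covered / n_seeds,
        "median_hr_estimate": float(np.median(hrs)),
        "n_seeds": n_seeds,
    }


def logrank_type1_error(seed: int = 0, reps: int = 500, n: int = 200,
                        alpha: float = 0.05) -> dict:
    """Empirical log-rank rejection rate under the null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(reps):
        frame = pd.DataFrame({
            "time": rng.exponential(50, n),
            "event": rng.random(n) < 0.7,
            "group": rng.integers(0, 2, n),
        })
        rejections += km_logrank(frame, "group", "time", "event").p_value < alpha
    return {"type1_error": rejections / reps, "reps": reps}


def end_to_end_favorable(seed: int = 0, n_seeds: int = 10, n_samples: int = 90) -> dict:
    """Full pipeline on the reference-shaped scenario.

    For each seed: simulate the default cohort (three subgroups, HR 3.2),
    run the pipeline from the segment tables, and check that the estimated
    instability-high (favorable) subgroup has the largest Kaplan-Meier
    survival estimate at the cohort's median follow-up.
    """
    hits = 0
    logrank_ps = []
    for i in range(n_seeds):
        s = _sub_seed(seed, i)
        with tempfile.TemporaryDirectory() as td:
            cfg = GenerativeConfig(n_samples=n_samples, seed=s)
            profiles, frame, _ = generate_cohort(cfg)
            write_seg(profiles, os.path.join(td, "segs.tsv"))
            frame.to_csv(os.path.join(td, "clinical.tsv"), sep="\t")
            cfg.genome.to_yaml(os.path.join(td, "genome.yaml"))
            rc = RunConfig(
                outdir=os.path.join(td, "run"), seed=s,
                segs=os.path.join(td, "segs.tsv"),
                clinical=os.path.join(td, "clinical.tsv"),
                genome_yaml=os.path.join(td, "genome.yaml"),
                k_signatures=cfg.K, nmf_runs=10,
                mixture_k_max=6, mixture_n_init=3,
            )
            run_pipeline(rc)
            labels = pd.read_csv(os.path.join(td, "run", "labels.tsv"),
                                 sep="\t", index_col=0)
            merged = frame.join(labels, how="inner")
            km = km_logrank(merged, "subgroup", "time_months", "event_css")
            surv = km.survival_at(float(merged["time_months"].median()))
            hits += max(surv, key=surv.get) == "Sig6high"
            logrank_ps.append(km.p_value)
    return {
        "favorable_on_top_frac": hits / n_seeds,
        "median_logrank_p": float(np.median(logrank_ps)),
        "n_seeds": n_seeds,
    }
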