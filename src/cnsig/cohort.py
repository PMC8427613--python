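"""Reference cohort description: the discovery cohort's printed
clinicopathological counts, and helpers recomputing the proportions.

The counts are those reported for the 90-patient upper-tract urothelial
carcinoma discovery cohort; they serve as worked-example inputs for the
proportion arithmetic and as the marginal frequencies the synthetic
cohort generator targets for its categorical covariates.
"""

from __future__ import annotations

import pandas as pd

REFERENCE_COHORT_SIZE = 90

# characteristic -> count among the 90 patients
REFERENCE_COHORT_COUNTS: dict[str, int] = {
    "gender_female": 55,
    "gender_male": 35,
    "smoking": 16,
    "aa_intake": 27,
    "synchronous_bladder_cancer": 5,
    "history_bladder_cancer": 9,
    "location_pelvis": 58,
    "location_ureter": 32,
    "multifocality": 12,
    "size_ge3cm": 52,
    "architecture_papillary": 64,
    "architecture_sessile": 26,
    "t_stage_ta": 1,
    "t_stage_t1": 42,
    "t_stage_t2": 25,
    "t_stage_t3": 20,
    "t_stage_t4": 2,
    "grade_low": 25,
    "grade_high": 65,
    "n_stage_n0_nx": 83,
    "cancer_related_death": 28,
    "overall_death": 30,
    "metastasis": 28,
    "bladder_recurrence": 19,
    "cancer_progression": 41,
}

# muscle-invasive disease = T2 or higher
MUSCLE_INVASIVE_STAGES = ("t_stage_t2", "t_stage_t3", "t_stage_t4")


def proportion_pct(count: int, total: int = REFERENCE_COHORT_SIZE, ndigits: int = 1) -> float:
    """Percentage of ``count`` out of ``total``, rounded for reporting."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)


def muscle_invasive_count(counts: dict[str, int] = REFERENCE_COHORT_COUNTS) -> int:
    return sum(counts[k] for k in MUSCLE_INVASIVE_STAGES)


def reference_cohort_summary() -> pd.DataFrame:
    """Counts and recomputed percentages for the reference cohort table."""
    rows = [{"characteristic": k, "count": v,
             "pct": proportion_pct(v)} for k, v in REFERENCE_COHORT_COUNTS.items()]
    rows.append({
        "characteristic": "muscle_invasive",
        "count": muscle_invasive_count(),
        "pct": proportion_pct(muscle_invasive_count()),
    })
    return pd.DataFrame(rows).set_index("characteristic")
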