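# cnsig

Copy-number (CN) signature analysis for tumor cohorts — built for the
upper-tract urothelial carcinoma (UTUC) setting, where shallow
whole-genome or cfDNA copy-number profiles carry prognostic information
that tumor stage and grade miss, but applicable to any cohort of
absolute-CN segment tables.

`cnsig` takes per-sample segment profiles (or raw binned read counts,
which it segments itself) through the full CN-signature protocol:

1. **Segmentation** — circular binary segmentation (CBS) of normalized
   binned counts into constant-CN segments.
2. **Six CN features** — per sample, event multisets for segment size,
   segment CN, CN change point, breakpoints per 10 Mb, breakpoints per
   chromosome arm, and oscillating-CN chain lengths.
3. **Mixture components** — cohort-level Gaussian/Poisson mixtures per
   feature (EM, BIC-selected k); each sample becomes a vector of summed
   posterior component memberships.
4. **Signatures** — non-negative matrix factorization (generalized
   Kullback–Leibler objective) of the sample × component matrix into
   signature definitions W (columns sum to 1) and per-sample exposure
   proportions; rank-selection diagnostics; max-proportion allocation;
   NNLS projection of frozen signatures onto new cohorts.
5. **Instability** — sample ploidy and wGII, the mean over the 22
   autosomes of the fraction of each chromosome whose CN deviates from
   ploidy.
6. **Stratification** — the three prognostic subgroups: quiet genomes
   (wGII < 0.1, "wGIIlow", worst outcome), then a median split of the
   instability-signature exposure into "Sig6high" (favorable) and
   "Sig6low"; external cohorts are projected via Spearman correlation
   with the reference signature (lowest third dropped, median split).
7. **Survival & association** — Kaplan–Meier + log-rank, Cox proportional
   hazards (Efron ties), chi-square, rank tests, exposure–activity
   Spearman matrices.

A synthetic-cohort generator (`cnsig.simulate`) produces cohorts with the
exact generative structure the analysis assumes — Dirichlet-mixed
signature exposures, per-feature mixture components, consistent segment
profiles, and proportional-hazards survival tied to the latent subgroup —
with full ground truth, so every stage is testable without
controlled-access patient data.

## Worked example

Simulate the reference-shaped cohort (n = 90, three latent signatures,
20% quiet genomes, subgroup hazard ratio 3.2) and run the analysis:

```python
from cnsig import (extract_cohort, km_logrank, wgii_cohort, classify_cohort)
from cnsig.simulate import GenerativeConfig, generate_cohort
from cnsig.mixtures import FeatureMixtureModel
from cnsig.signatures import CNSignatureModel, identify_instability_signature

cfg = GenerativeConfig(n_samples=90, seed=23)
profiles, clinical, truth = generate_cohort(cfg)
events = extract_cohort(profiles, cfg.genome)

mix = FeatureMixtureModel(events).fit(k_range=range(1, 7), n_init=3, seed=23)
result = CNSignatureModel(mix.matrix).fit(k=3, n_runs=15, seed=23)
print(result.summary())

wg = wgii_cohort(profiles, cfg.genome)
sig6 = identify_instability_signature(result.W, mix.model)
cls = classify_cohort(result.exposures[sig6], wg["wgii"])
frame = clinical.join(cls.labels)
km = km_logrank(frame, "subgroup", "time_months", "event_css")
print(f"log-rank statistic {km.statistic:.2f}, p = {km.p_value:.4f}")
```

Output (abridged):

```
CN signature model: K=3, 24 components, 90 samples
KL reconstruction error: 37.7104
Samples allocated by maximal exposure:
  Sig1     44
  Sig2     32
  Sig3     14
...
instability signature: Sig2
realized Sig6 split: 0.316
subgroup
Sig6high    39
Sig6low     38
wGIIlow     13

log-rank statistic 17.92, p = 0.0001
KM survival at median follow-up: {'Sig6high': 0.74, 'Sig6low': 0.4, 'wGIIlow': 0.54}
```

Reading this: the mixture stage found 24 components across the six
features; the factorization yields three signatures with exposure
proportions per sample; the signature whose definition implies the
highest breakpoint/oscillation intensity (here `Sig2`) is the instability
("Sig6") analogue; 13 quiet genomes form the wGIIlow subgroup and the
remaining 77 are halved around their instability exposure (realized split
0.316). The log-rank test separates the subgroups (p = 1e-4), and the
instability-high subgroup has the best Kaplan–Meier survival at median
follow-up — the favorable-prognosis pattern the stratification is built
to detect, with the quiet-genome group doing poorly despite its low
instability.

The same flow runs from the shell:

```bash
cnsig simulate --n 90 --seed 23 -o sim/
cnsig pipeline --config run.yaml           # segment -> ... -> survive
cnsig wgii --segs sim/segs.tsv --genome sim/genome.yaml -o wgii.tsv
```

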