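"""End-to-end pipeline orchestration.

Stages run in order — segment, features, components, signatures, wgii,
classify, survive — communicating only through documented file formats
(TSV/JSON/YAML), so any stage can be re-run independently and frozen
models can be reused across cohorts. A manifest records versions, seeds
and input hashes. In project mode a frozen signature model directory is
required and exposures come from NNLS projection instead of a fresh NMF.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .cbs import cbs_segment
from .features import extract_cohort, load_events, save_events
from .genome import GenomeBuild, synthetic_genome
from .instability import wgii_cohort
from .mixtures import ComponentModel, FeatureMixtureModel, posterior_encode
from .segments import read_counts, read_seg, write_seg
from .signatures import CNSignatureModel, SignatureResult, quantify_fixed
from .stratify import classify_cohort
from .survival import km_logrank

STAGES = ("segment", "features", "components", "signatures", "wgii", "classify", "survive")


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    # inputs: either binned counts (+ bins) to segment, or a segment table
    counts: str | None = None
    bins: str | None = None
    segs: str | None = None
    clinical: str | None = None
    genome_yaml: str | None = None
    # stage parameters
    alpha: float = 0.01
    min_width: int = 2
    n_perm: int = 200
    merge_tol: float = 0.3
    k_signatures: int = 6
    nmf_runs: int = 50
    mixture_k_max: int = 10
    mixture_n_init: int = 5
    wgii_cutoff: float = 0.1
    endpoint_time: str = "time_months"
    endpoint_event: str = "event_css"
    # project mode: reuse a frozen signature model + component model
    mode: str = "extract"  # extract | project
    sigmodel_dir: str | None = None
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        doc = {k: v for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline; returns the manifest dict (also written to
    ``manifest.json`` in the output directory)."""
    os.makedirs(config.outdir, exist_ok=True)
    genome = (GenomeBuild.from_yaml(config.genome_yaml)
              if config.genome_yaml else synthetic_genome())
    if config.mode == "project" and not config.sigmodel_dir:
        raise ValueError("project mode requires sigmodel_dir")

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "stages": [],
        "inputs": {},
    }
    for key in ("counts", "bins", "segs", "clinical"):
        path = getattr(config, key)
        if path:
            manifest["inputs"][key] = {"path": str(path), "sha256_16": _hash_file(path)}

    def out(name: str) -> str:
        return os.path.join(config.outdir, name)

    stage = "segment"
    try:
        if config.counts:
            counts = read_counts(config.counts, config.bins)
            profiles = cbs_segment(
                counts, genome, alpha=config.alpha, min_width=config.min_width,
                n_perm=config.n_perm, seed=config.seed, merge_tol=config.merge_tol,
            )
            write_seg(profiles, out("segs.tsv"))
            manifest["stages"].append(stage)
        elif config.segs:
            profiles = read_seg(config.segs, genome)
            manifest["stages"].append(f"{stage} (loaded from segment table)")
        else:
            raise ValueError("need either counts+bins or a segment table")

        stage = "features"
        events = extract_cohort(profiles, genome)
        save_events(events, out("events.json"))
        manifest["stages"].append(stage)

        stage = "components"
        if config.mode == "project":
            model = ComponentModel.load(os.path.join(config.sigmodel_dir, "components.json"))
            matrix = posterior_encode(events, model)
        else:
            result = FeatureMixtureModel(events).fit(
                k_range=range(1, config.mixture_k_max + 1),
                n_init=config.mixture_n_init, seed=config.seed,
            )
            model, matrix = result.model, result.matrix
            model.save(out("components.json"))
        matrix.to_csv(out("component_matrix.tsv"), sep="\t")
        manifest["stages"].append(stage)
        manifest["n_components"] = model.n_components

        stage = "signatures"
        if config.mode == "project":
            ref = SignatureResult.load(config.sigmodel_dir)
            exposures = quantify_fixed(matrix, ref.W)
            W = ref.W
        else:
            sig = CNSignatureModel(matrix).fit(
                k=config.k_signatures, n_runs=config.nmf_runs, seed=config.seed)
            sig.save(config.outdir)
            exposures, W = sig.exposures, sig.W
        exposures.to_csv(out("exposures.tsv"), sep="\t")
        manifest["stages"].append(stage)
        manifest["k_signatures"] = W.shape[1]

        stage = "wgii"
        wg = wgii_cohort(profiles, genome)
        wg.to_csv(out("wgii.tsv"), sep="\t")
        manifest["stages"].append(stage)

        stage = "classify"
        from .signatures import identify_instability_signature

        sig6_name = identify_instability_signature(W, model)
        cls = classify_cohort(exposures[sig6_name], wg["wgii"],
                              wgii_cutoff=config.wgii_cutoff)
        labels = cls.labels.to_frame()
        labels.to_csv(out("labels.tsv"), sep="\t")
        manifest["stages"].append(stage)
        manifest["sig6_signature"] = str(sig6_name)
        manifest["realized_sig6_split"] = cls.realized_split

        stage = "survive"
        if config.clinical:
            clinical = pd.read_csv(config.clinical, sep="\t", index_col="sample")
            frame = clinical.join(labels, how="inner")
            km = km_logrank(frame, "subgroup", config.endpoint_time, config.endpoint_event)
            surv = {
                "logrank_statistic": km.statistic,
                "logrank_p": km.p_value,
                "median_survival": km.medians,
            }
            with open(out("survival.json"), "w") as fh:
                json.dump(surv, fh, indent=1)
            for group, curve in km.curves.items():
                curve.to_csv(out(f"km_{group}.tsv"), sep="\t", index=False)
            manifest["stages"].append(stage)
        else:
            manifest["stages"].append(f"{stage} (skipped: no clinical table)")
    except Exception as exc:  # partial outputs stay on disk for inspection
        raise StageError(stage, exc) from exc

    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
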