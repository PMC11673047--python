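"""End-to-end experiment driver.

Stages mirror the study workflow: simulate train/external cohorts ->
train the harmonizer (target = iterative reconstruction) -> harmonize the
external cohort -> extract features from original and harmonized stacks ->
redundancy exclusion -> region- and patient-based reproducibility analyses
-> standard-deviation maps and reports.  Every stage persists CSV/JSON
artifacts so each report value can be recomputed from disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as cio
from .harmonizer import (
    HarmonizerSpec,
    TrainedHarmonizer,
    harmonize,
    identity_harmonizer,
    train,
)
from .phantom import (
    DEFAULT_PROTOCOLS,
    GeometryConfig,
    ProtocolStack,
    ROISet,
    make_cohort,
)
from .radiomics import ExtractionParams, build_schema, extract_cohort_features
from .reproducibility import (
    ICCConfig,
    PatientSummary,
    RegionSummary,
    icc_by_patient,
    icc_by_roi,
    patient_based_analysis,
    redundancy_exclusion,
    region_based_analysis,
)
from .stdmap import std_map

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentConfig:
    n_train: int = 8
    n_external: int = 8
    seed: int = 0
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    extraction: ExtractionParams = field(default_factory=ExtractionParams)
    icc: ICCConfig = field(default_factory=ICCConfig)
    harmonizer: Optional[HarmonizerSpec] = None  # None -> default spec with seed
    identity_harmonizer: bool = False
    apply_redundancy_exclusion: bool = True

    def resolved_harmonizer(self) -> HarmonizerSpec:
        return self.harmonizer or HarmonizerSpec(seed=self.seed)


@dataclass
class ReportBundle:
    region: RegionSummary
    patient: PatientSummary
    redundancy: "object"
    stdmap_mean_original: float
    stdmap_mean_harmonized: float
    out_dir: Path
    model: TrainedHarmonizer

    def summary_dict(self) -> dict:
        return {
            "region_table": self.region.table.to_dict(orient="records"),
            "patient_mean_original": self.patient.mean_original,
            "patient_sd_original": self.patient.sd_original,
            "patient_mean_harmonized": self.patient.mean_harmonized,
            "patient_sd_harmonized": self.patient.sd_harmonized,
            "patient_mean_gain": self.patient.mean_gain,
            "n_features_analyzed": self.patient.n_features,
            "excluded_groups": list(self.redundancy.excluded_groups),
            "retained_count": self.redundancy.retained_count,
            "stdmap_mean_original": self.stdmap_mean_original,
            "stdmap_mean_harmonized": self.stdmap_mean_harmonized,
        }


def _body_mask(stack: ProtocolStack) -> np.ndarray:
    # soft-tissue pixels; excludes surrounding air where every protocol agrees
    return stack.images[stack.target_label] > -500


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> ReportBundle:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schema = build_schema()
    cfg_icc = config.icc

    stage = "simulate"
    try:
        ss = np.random.SeedSequence(config.seed)
        seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3)]
        train_cohort = make_cohort(config.n_train, DEFAULT_PROTOCOLS,
                                   config.geometry, seed=seeds[0])
        ext_cohort = make_cohort(config.n_external, DEFAULT_PROTOCOLS,
                                 config.geometry, seed=seeds[1])
        # external ids must not collide with training ids
        for st, _ in ext_cohort:
            st.subject_id = "ext_" + st.subject_id

        stage = "train"
        if config.identity_harmonizer:
            model = identity_harmonizer(config.resolved_harmonizer())
        else:
            spec = config.resolved_harmonizer()
            model = train(train_cohort, spec)
        pd.DataFrame(model.history).to_csv(out / "training_history.csv", index=False)

        stage = "harmonize"
        harmonized = [(harmonize(model, st), rois) for st, rois in ext_cohort]

        stage = "extract"
        feats_train = extract_cohort_features(train_cohort, schema, config.extraction)
        feats_ext = extract_cohort_features(ext_cohort, schema, config.extraction)
        feats_harm = extract_cohort_features(harmonized, schema, config.extraction)
        cio.write_table(feats_train, out / "features_train_original.csv")
        cio.write_table(feats_ext, out / "features_external_original.csv")
        cio.write_table(feats_harm, out / "features_external_harmonized.csv")

        stage = "redundancy"
        train_icc = icc_by_roi(feats_train, cfg_icc)
        ext_patient_icc = icc_by_patient(feats_ext, cfg_icc)
        report = redundancy_exclusion(train_icc, ext_patient_icc, schema, cfg_icc)
        (out / "redundancy.json").write_text(json.dumps(report.to_json_dict(), indent=2))
        retained = (
            report.retained_features
            if config.apply_redundancy_exclusion
            else schema.feature_ids
        )

        stage = "region_analysis"
        region = region_based_analysis(feats_ext, feats_harm, retained, cfg_icc)
        cio.write_table(region.table, out / "region_summary.csv")
        cio.write_table(region.icc_original, out / "icc_region_original.csv")
        cio.write_table(region.icc_harmonized, out / "icc_region_harmonized.csv")

        stage = "patient_analysis"
        patient = patient_based_analysis(feats_ext, feats_harm, retained, cfg_icc)
        cio.write_table(patient.per_patient, out / "patient_summary.csv")
        patient.heatmap_original.to_csv(out / "heatmap_original.csv")
        patient.heatmap_harmonized.to_csv(out / "heatmap_harmonized.csv")
        _save_heatmap_png(patient, out)

        stage = "stdmap"
        mask0 = _body_mask(ext_cohort[0][0])
        sm_o = float(np.mean([std_map(st).std_image[_body_mask(st)].mean()
                              for st, _ in ext_cohort]))
        sm_h = float(np.mean([
            std_map(h).std_image[_body_mask(o)].mean()
            for (h, _), (o, _) in zip(harmonized, ext_cohort)
        ]))

        stage = "report"
        bundle = ReportBundle(region, patient, report, sm_o, sm_h, out, model)
        (out / "report.json").write_text(json.dumps(bundle.summary_dict(), indent=2))
        return bundle
    except Exception:
        logger.exception("experiment failed at stage %s (partial outputs in %s)",
                         stage, out)
        raise


def _save_heatmap_png(patient: PatientSummary, out: Path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 1, figsize=(10, 5), constrained_layout=True)
        for ax, (hm, title) in zip(
            axes,
            [(patient.heatmap_original, "original"),
             (patient.heatmap_harmonized, "harmonized")],
        ):
            ax.imshow(hm.to_numpy(), aspect="auto", vmin=0, vmax=1, cmap="viridis")
            ax.set_title(f"per-patient ICC, {title}")
            ax.set_xlabel("feature")
            ax.set_ylabel("patient")
        fig.savefig(out / "icc_heatmaps.png", dpi=120)
        plt.close(fig)
    except Exception:  # plotting must never sink the pipeline
        logger.warning("heatmap PNG rendering failed", exc_info=True)
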