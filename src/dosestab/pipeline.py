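"""End-to-end study orchestration: cohort -> error doses -> features -> report.

The full default protocol per patient is 81 dose volumes (20 replicates for
each of the fraction groups 2/10/20/30 plus the error-free original), each
analysed in four ROIs with 93 features.  Per-patient feature tables are
written as CSV and skipped on re-run when already complete, so an
interrupted extraction resumes where it stopped.  A JSON manifest records
the configuration, the seed and per-stage counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .dosiomics import ExtractorConfig, extract_features
from .errors import ErrorModel, ProtocolSpec, run_error_protocol
from .grids import ROI_LABELS, read_volume
from .phantom import PhantomSettings, generate_cohort
from .study import StabilityResults, StabilityStudy

log = logging.getLogger("dosestab")


@dataclass
class RunConfig:
    """Everything a full study run depends on, loadable from YAML."""

    n_patients: int = 15
    seed: int = 1
    cohort_dir: str | None = None  # None -> synthetic cohort
    output_dir: str = "dosestab_out"
    phantom: PhantomSettings = field(default_factory=PhantomSettings)
    error_model: ErrorModel = field(default_factory=ErrorModel)
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    extractor: ExtractorConfig = field(default_factory=ExtractorConfig)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for name, sub_cls in (
            ("phantom", PhantomSettings),
            ("error_model", ErrorModel),
            ("protocol", ProtocolSpec),
            ("extractor", ExtractorConfig),
        ):
            sub = raw.pop(name, None)
            if sub is not None:
                for key in ("shape", "spacing", "mean", "sd", "fraction_groups",
                            "gtv_axis_ratios", "heart_semiaxes_mm",
                            "target_center_mm"):
                    if isinstance(sub.get(key), list):
                        sub[key] = tuple(sub[key])
                kwargs[name] = sub_cls(**sub)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(raw)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_cohort(config: RunConfig):
    """Return a list of (patient_id, DoseGrid, {label: RoiMask})."""
    if config.cohort_dir is None:
        protocol = dataclasses.replace(config.protocol, base_seed=config.seed)
        phantom = config.phantom
        cohort = generate_cohort(config.n_patients, config.seed, phantom)
        return protocol, [
            (p, grid, masks) for p, (grid, masks) in enumerate(cohort)
        ]
    patients = []
    p = 0
    while True:
        dose_path = None
        for ext in (".nrrd", ".nii.gz", ".nii"):
            cand = os.path.join(config.cohort_dir, f"patient{p:02d}_dose{ext}")
            if os.path.exists(cand):
                dose_path = cand
                break
        if dose_path is None:
            break
        grid = read_volume(dose_path, kind="dose")
        masks = {}
        for label in ROI_LABELS:
            ext = dose_path[dose_path.index(".nrrd" if dose_path.endswith(".nrrd") else ".nii"):]
            mask_path = os.path.join(
                config.cohort_dir, f"patient{p:02d}_{label.lower()}{ext}"
            )
            if not os.path.exists(mask_path):
                raise FileNotFoundError(f"missing ROI mask {mask_path}")
            masks[label] = read_volume(mask_path, kind="mask", label=label)
        patients.append((p, grid, masks))
        p += 1
    if not patients:
        raise FileNotFoundError(
            f"no patientNN_dose volumes found in {config.cohort_dir}"
        )
    protocol = dataclasses.replace(config.protocol, base_seed=config.seed)
    return protocol, patients


def extract_patient_features(
    patient_id: int,
    grid,
    masks,
    protocol: ProtocolSpec,
    model: ErrorModel,
    extractor: ExtractorConfig,
) -> pd.DataFrame:
    """The tidy feature table for one patient over the full error protocol."""
    doses = run_error_protocol(grid, protocol, model, patient=patient_id)
    frames = []
    for dose_key, dose in doses.items():
        if dose_key == "original":
            group, rep = "original", -1
        else:
            group, rep = dose_key
        for label, mask in masks.items():
            fv = extract_features(dose, mask, extractor)
            df = fv.to_frame()
            df.insert(0, "replicate", rep)
            df.insert(0, "fraction_group", str(group))
            df.insert(0, "roi", label)
            df.insert(0, "patient", patient_id)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _expected_rows(protocol: ProtocolSpec, n_rois: int) -> int:
    n_doses = len(protocol.fraction_groups) * protocol.replicates + 1
    from .dosiomics import N_FEATURES

    return n_doses * n_rois * N_FEATURES


def run_study(config: RunConfig) -> StabilityResults:
    """Run the complete study and write all outputs under the output dir."""
    t0 = time.time()
    outdir = config.output_dir
    feat_dir = os.path.join(outdir, "features")
    os.makedirs(feat_dir, exist_ok=True)

    protocol, patients = _load_cohort(config)
    model = config.error_model
    warnings_count = 0

    frames = []
    for pid, grid, masks in patients:
        path = os.path.join(feat_dir, f"patient{pid:02d}_features.csv")
        expected = _expected_rows(protocol, len(masks))
        if os.path.exists(path):
            df = pd.read_csv(path)
            if len(df) == expected:
                log.info("patient %d: reusing existing features", pid)
                frames.append(df)
                continue
            log.warning(
                "patient %d: stale feature file (%d rows, expected %d); redoing",
                pid, len(df), expected,
            )
        log.info("patient %d: simulating %d dose volumes and extracting", pid,
                 len(protocol.fraction_groups) * protocol.replicates + 1)
        df = extract_patient_features(
            pid, grid, masks, protocol, model, config.extractor
        )
        df.to_csv(path, index=False)
        # analyse the persisted table so a fresh run and a resumed run feed
        # byte-identical inputs into the statistics
        frames.append(pd.read_csv(path))

    features = pd.concat(frames, ignore_index=True)
    study = StabilityStudy(features)
    results = study.fit()
    table_paths = results.save_tables(outdir)
    results.plot_cv_categories(os.path.join(outdir, "cv_categories.png"))

    n_invalid = int((~features["valid"]).sum())
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "patients": len(patients),
        "fraction_groups": list(protocol.fraction_groups),
        "replicates": protocol.replicates,
        "dose_volumes_per_patient": len(protocol.fraction_groups) * protocol.replicates + 1,
        "feature_rows": int(len(features)),
        "invalid_feature_rows": n_invalid,
        "pd_exclusions": int(results.pd_table["n_excluded"].sum()),
        "cv_undefined": int(results.cv_table["n_undefined"].sum()),
        "translation_warnings": warnings_count,
        "tables": table_paths,
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(os.path.join(outdir, "summary.txt"), "w") as fh:
        fh.write(results.summary() + "\n")
    return results
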