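"""End-to-end analysis pipeline: frames -> reorientation -> normalisation ->
hotspot metrics -> surfaces.

``analyze_volumes`` is the in-memory pipeline; ``run_analyze`` wraps it with
file I/O for the CLI, and ``run_compare`` puts two analyses side by side.

The default geometry (all boxes in femoral-frame coordinates, mm):

* analysis bounds — the reorientation target grid around the knee and the
  distal shaft;
* reference region — a mid-shaft box, PROX 80..130, spanning the full bone
  cross-section: clinically neutral bone, away from any articular surface;
* ROI — an anterior box over the patellofemoral compartment, reaching just
  past the joint line so uptake spreading toward the tibiofemoral
  compartment is captured.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .frames import (
    AnatomicFrame,
    LandmarkSet,
    femoral_frame,
    frame_rotation,
    tibial_frame,
)
from .hotspot import hotspot_mask, hotspot_metrics
from .normalization import (
    NormalizationModel,
    ReferenceRegion,
    histogram_triplet,
    region_stats,
    threshold_from_model,
)
from .surface import DEFAULT_BONE_LEVEL_HU, extract_isosurface, scene_export
from .volume_io import ImageVolume, read_volume, resample_to_frame, write_volume

logger = logging.getLogger("orthospect")

DEFAULT_REF_BOUNDS = ((-25.0, -25.0, 80.0), (25.0, 25.0, 130.0))
DEFAULT_ROI_BOUNDS = ((-40.0, 5.0, -45.0), (40.0, 50.0, 45.0))
DEFAULT_ANALYSIS_BOUNDS = ((-60.0, 60.0), (-60.0, 60.0), (-60.0, 140.0))
DEFAULT_SPACING = (3.0, 3.0, 3.0)


@dataclass
class AnalysisConfig:
    """Everything one analysis run needs; loadable from TOML or JSON."""

    ct_path: str | None = None
    spect_path: str | None = None
    landmarks_path: str | None = None
    output_dir: str = "orthospect_out"
    ref_bounds: tuple = DEFAULT_REF_BOUNDS
    ref_frame_tag: str = "femoral"
    roi_bounds: tuple = DEFAULT_ROI_BOUNDS
    roi_frame_tag: str = "femoral"
    norm_mode: str = "scale_by_mean"
    threshold_rule: dict = field(default_factory=lambda: {"k_times_mean": 3.0})
    analysis_bounds: tuple = DEFAULT_ANALYSIS_BOUNDS
    analysis_spacing: tuple = DEFAULT_SPACING
    bone_level: float = DEFAULT_BONE_LEVEL_HU
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        path = Path(path)
        if path.suffix.lower() == ".toml":
            import tomllib

            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        elif path.suffix.lower() == ".json":
            with open(path) as fh:
                data = json.load(fh)
        else:
            raise ValueError(f"config must be .toml or .json, got {path.name}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = {}
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            d[name] = np.asarray(v).tolist() if isinstance(v, (tuple, np.ndarray)) else v
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def analyze_volumes(
    ct: ImageVolume,
    spect: ImageVolume,
    landmarks: LandmarkSet,
    config: AnalysisConfig | None = None,
) -> dict:
    """Run the full pipeline in memory.

    Steps: build the femoral (and, if the talus landmark is present, tibial)
    frame; measure realignment versus the scanner frame; reorient the SPECT
    into the femoral frame; take reference-region statistics; derive the raw
    threshold from the configured rule; segment the hotspot inside the ROI;
    compute metrics; build the histogram triplet; extract bone and hotspot
    isosurfaces in anatomic coordinates.
    """
    cfg = config or AnalysisConfig()
    fem = femoral_frame(landmarks)
    frames: dict[str, AnatomicFrame] = {"femoral": fem}
    if landmarks.talus_centre is not None:
        frames["tibial"] = tibial_frame(fem, fem.origin, landmarks.talus_centre)
    realign = frame_rotation(AnatomicFrame.identity(), fem)

    spect_anat = resample_to_frame(spect, fem, cfg.analysis_spacing, cfg.analysis_bounds)

    ref_region = ReferenceRegion(np.asarray(cfg.ref_bounds), frame_tag=cfg.ref_frame_tag)
    roi = ReferenceRegion(np.asarray(cfg.roi_bounds), frame_tag=cfg.roi_frame_tag)
    ref_frame = frames.get(cfg.ref_frame_tag) if cfg.ref_frame_tag != "world" else None
    roi_frame = frames.get(cfg.roi_frame_tag) if cfg.roi_frame_tag != "world" else None

    ref = region_stats(spect_anat, ref_region, ref_frame)
    model = NormalizationModel(mode=cfg.norm_mode, ref=ref)
    threshold = threshold_from_model(model, cfg.threshold_rule)

    mask = hotspot_mask(spect_anat, roi, threshold, roi_frame)
    metrics = hotspot_metrics(spect_anat, mask, model, fem, ref, threshold_raw=threshold)
    hist = histogram_triplet(spect_anat, ref_region, roi, fem)

    bone_mesh = extract_isosurface(ct, cfg.bone_level, frame=fem, label="bone")
    hot_mesh = extract_isosurface(spect_anat, threshold, frame=fem, label="hotspot")

    return {
        "config": cfg,
        "frames": frames,
        "realignment": realign,
        "spect_anatomic": spect_anat,
        "reference_stats": ref,
        "model": model,
        "threshold_raw": threshold,
        "mask": mask,
        "metrics": metrics,
        "histograms": hist,
        "bone_mesh": bone_mesh,
        "hotspot_mesh": hot_mesh,
    }


def _write_histogram_csv(hist: dict, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["bin_left", "bin_right", "global", "saved", "local"])
        edges = hist["edges"]
        for i in range(len(edges) - 1):
            w.writerow(
                [edges[i], edges[i + 1], hist["global"][i], hist["saved"][i], hist["local"][i]]
            )


def run_analyze(config: AnalysisConfig) -> dict:
    """File-based pipeline run: load inputs, analyse, write every artifact.

    Writes frames JSON, reference stats JSON, histogram-triplet CSV, hotspot
    metrics JSON + CSV, the hotspot mask as NIfTI, bone/hotspot meshes as
    PLY with a manifest, and a run log carrying the config hash.
    """
    for attr, label in (
        ("ct_path", "CT volume"),
        ("spect_path", "SPECT volume"),
        ("landmarks_path", "landmarks"),
    ):
        p = getattr(config, attr)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"{label} file not found: {p}")

    ct = read_volume(config.ct_path, modality="CT")
    spect = read_volume(config.spect_path, modality="SPECT")
    landmarks = LandmarkSet.from_json(config.landmarks_path)

    res = analyze_volumes(ct, spect, landmarks, config)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, frame in res["frames"].items():
        frame.to_json(out / f"frame_{name}.json")
    with open(out / "reference_stats.json", "w") as fh:
        json.dump(res["reference_stats"].to_dict(), fh, indent=2)
    _write_histogram_csv(res["histograms"], out / "histogram_triplet.csv")

    metrics_dict = res["metrics"].to_dict()
    metrics_dict["realignment_total_deg"] = res["realignment"]["total_deg"]
    metrics_dict["realignment_about_PROX_deg"] = res["realignment"]["about_PROX_deg"]
    metrics_dict["config_hash"] = config.digest()
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics_dict, fh, indent=2, sort_keys=True)
    with open(out / "metrics.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(list(metrics_dict))
        w.writerow([metrics_dict[k] for k in metrics_dict])

    write_volume(res["mask"].to_volume(), out / "hotspot_mask.nii.gz")
    if not res["hotspot_mesh"].is_empty:
        scene_export(res["bone_mesh"], res["hotspot_mesh"], out / "scene.json")

    with open(out / "run_log.txt", "w") as fh:
        import numpy, scipy, skimage

        fh.write(f"config_hash: {config.digest()}\n")
        fh.write(f"numpy {numpy.__version__}, scipy {scipy.__version__}, "
                 f"scikit-image {skimage.__version__}\n")
        fh.write(json.dumps(config.to_dict(), indent=2, sort_keys=True))
    logger.info("analysis written to %s (config %s)", out, config.digest())
    return res


def compare_results(res_a: dict, res_b: dict, names: tuple[str, str] = ("A", "B")) -> dict:
    """Side-by-side table of normalised metrics for two analyses.

    Comparisons are only meaningful under identical normalisation modes and
    threshold rules, which is enforced.
    """
    ca, cb = res_a["config"], res_b["config"]
    if ca.norm_mode != cb.norm_mode or ca.threshold_rule != cb.threshold_rule:
        raise ValueError("comparison requires identical normalisation mode and threshold rule")
    ma, mb = res_a["metrics"], res_b["metrics"]
    rows = {}
    for key in ("max_ratio", "mean_ratio", "volume_mm3", "voxel_count"):
        va, vb = getattr(ma, key), getattr(mb, key)
        rows[key] = {
            names[0]: va,
            names[1]: vb,
            "difference": None if va is None or vb is None else vb - va,
            "ratio": None if not va else (None if vb is None else vb / va),
        }
    return {
        "names": list(names),
        "threshold_rule": ca.threshold_rule,
        "norm_mode": ca.norm_mode,
        "rows": rows,
    }


def run_compare(config_a: AnalysisConfig, config_b: AnalysisConfig) -> dict:
    """Run two file-based analyses and compare their normalised metrics."""
    res_a = run_analyze(config_a)
    res_b = run_analyze(config_b)
    report = compare_results(res_a, res_b)
    out = Path(config_a.output_dir)
    with open(out / "comparison.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
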