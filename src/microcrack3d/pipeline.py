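"""End-to-end orchestration: phantom or volume in, reports out.

A :class:`PipelineConfig` gathers every knob of the chain (preprocessing,
segmentation, classification, 2D sectioning); :func:`run_pipeline` executes
phantom generation (or volume loading), preprocessing, segmentation,
quantification and 2D sectioning, and writes the label volume, per-object
CSV, specimen report, 2D report and a run log with per-stage voxel counts
and the config hash.  :func:`score_detection` scores a predicted label map
against a ground-truth one.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import phantom as ph
from . import preprocess, quantify, section2d, segmentation
from .volume_io import read_volume, write_volume

__all__ = [
    "PipelineConfig",
    "ConfigValidationError",
    "run_pipeline",
    "score_detection",
]

log = logging.getLogger("microcrack3d")


class ConfigValidationError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated configuration for a full run.

    Exactly one of ``input_path`` / ``phantom`` must be set.  The default
    profile exposes the small set of tunables that matter: the bone
    threshold, the planarity scale, the hysteresis pair and the guided-
    filter spatial radius.
    """

    input_path: str | None = None
    phantom: ph.PhantomConfig | None = None
    voxel_size_um: float | None = None

    ring_enabled: bool = True
    ring_radial_smooth_um: float = 28.0
    norm_enabled: bool = True
    norm_window_um: float = 200.0
    norm_mode: str = "subtract"

    bone_threshold: float | str = "auto"
    planarity_sigma_um: float = 2.1
    hysteresis_low: float = 0.25
    hysteresis_high: float = 0.5
    spatial_radius_um: float = 2.8
    closing_radius_um: float = 14.0

    min_volume_um3: float = 500.0
    max_ratio: float = 1.0 / 3.0

    sections_averaged: int = 5
    sections_spacing: int = 128
    sections_n: int = 8
    sections_z0: int = 0
    run_sections: bool = True
    site_metrics: bool = True
    compute_smi: bool = True

    out_dir: str = "microcrack3d_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.input_path is None) == (self.phantom is None):
            raise ConfigValidationError(
                "exactly one of input_path / phantom must be given"
            )
        if self.hysteresis_low > self.hysteresis_high:
            raise ConfigValidationError(
                f"hysteresis low {self.hysteresis_low} exceeds high "
                f"{self.hysteresis_high}"
            )
        for name in ("planarity_sigma_um", "spatial_radius_um", "closing_radius_um"):
            if getattr(self, name) <= 0:
                raise ConfigValidationError(f"{name} must be > 0")
        if self.phantom is not None:
            self.phantom.validate()

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("phantom") is not None:
            p = dict(d["phantom"])
            if "lacunae" in p and isinstance(p["lacunae"], dict):
                p["lacunae"] = ph.LacunaSpec(
                    **{
                        k: tuple(v) if isinstance(v, list) else v
                        for k, v in p["lacunae"].items()
                    }
                )
            if "cracks" in p and isinstance(p["cracks"], dict):
                p["cracks"] = ph.CrackSpec(
                    **{
                        k: tuple(v) if isinstance(v, list) else v
                        for k, v in p["cracks"].items()
                    }
                )
            if "shape" in p:
                p["shape"] = tuple(p["shape"])
            d["phantom"] = ph.PhantomConfig(**p)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _setup_logging(level: str, out_dir: Path) -> None:
    log.setLevel(level.upper())
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(sh)
    fh = logging.FileHandler(out_dir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a result bundle dict.

    Outputs written under ``config.out_dir``: ``labels.tif`` (+sidecar),
    ``porosities.csv``, ``specimen_report.json``, ``sections2d.json``,
    ``run.log`` and ``config_used.yaml``.  Raises on the first stage error
    (the partial outputs written so far remain on disk, flagged in the log).
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(config.log_level, out_dir)
    chash = config.config_hash()
    log.info("config hash %s", chash)

    truth = None
    if config.phantom is not None:
        pconf = dataclasses.replace(config.phantom, seed=config.seed)
        vol, truth = ph.generate_phantom(pconf)
        log.info(
            "phantom %s voxels, BV/TV %.3f, %d truth objects",
            vol.data.shape, truth.bone_mask.mean(), len(truth.objects),
        )
    else:
        vol = read_volume(config.input_path, config.voxel_size_um)
        log.info("loaded %s (%s voxels)", config.input_path, vol.data.shape)

    if config.ring_enabled:
        vol = preprocess.remove_ring_artifacts(
            vol, radial_smooth_um=config.ring_radial_smooth_um
        )
        log.info("ring-artifact correction applied")
    if config.norm_enabled:
        vol = preprocess.normalize_intensity(
            vol, config.norm_window_um, config.norm_mode
        )
        log.info("intensity normalisation applied (%s)", config.norm_mode)

    seg = segmentation.segment_porosities(
        vol.data,
        vol.voxel_size_um,
        bone_threshold=config.bone_threshold,
        planarity_sigma_um=config.planarity_sigma_um,
        hysteresis_low=config.hysteresis_low,
        hysteresis_high=config.hysteresis_high,
        spatial_radius_um=config.spatial_radius_um,
        closing_radius_um=config.closing_radius_um,
    )
    log.info("segmentation counts: %s", seg["counts"])

    records = quantify.analyze_porosities(
        seg["labels"], vol.voxel_size_um, config.min_volume_um3, config.max_ratio
    )
    log.info("quantified %d porosities", len(records))

    env_thickness = None
    if config.site_metrics and any(r.cls == "microcrack" for r in records):
        env_thickness = quantify.thickness_map(
            seg["envelope"], vol.voxel_size_um, coarse=True
        )
        for r in records:
            if r.cls != "microcrack":
                continue
            try:
                r.tb_th_lo_um = quantify.local_trabecular_thickness(
                    env_thickness, seg["envelope"], r.centroid_um, r.width_um,
                    vol.voxel_size_um,
                )
                r.trab_shape = quantify.trabecular_shape(
                    seg["envelope"], r.centroid_um, r.width_um, vol.voxel_size_um
                )
            except quantify.SiteError as exc:
                log.warning("label %d: %s", r.label, exc)

    smi = (
        quantify.compute_smi(seg["envelope"], vol.voxel_size_um)
        if config.compute_smi
        else None
    )
    report = quantify.specimen_metrics(
        records, seg["porosity_mask"], seg["envelope"], vol.voxel_size_um, smi=smi
    )

    metrics2d = None
    if config.run_sections:
        try:
            sections = section2d.make_virtual_sections(
                vol,
                config.sections_averaged,
                config.sections_spacing,
                config.sections_n,
                config.sections_z0,
            )
            metrics2d = section2d.measure_sections(
                sections,
                bone_threshold=config.bone_threshold,
                trace_low=config.hysteresis_low,
                trace_high=config.hysteresis_high,
            )
            log.info("2D sections: %s", metrics2d.to_dict())
        except ValueError as exc:
            log.warning("2D sectioning skipped: %s", exc)

    # ---- outputs --------------------------------------------------------
    write_volume(seg["labels"], out_dir / "labels.tif", vol.voxel_size_um, kind="labels")
    df = quantify.records_to_dataframe(records)
    df.to_csv(out_dir / "porosities.csv", index=False)
    report_dict = {
        "config_hash": chash,
        **report.to_dict(),
        "trabecular_shape_note": "shape classes come from a local-topology heuristic",
    }
    (out_dir / "specimen_report.json").write_text(json.dumps(report_dict, indent=2))
    if metrics2d is not None:
        (out_dir / "sections2d.json").write_text(
            json.dumps(metrics2d.to_dict(), indent=2)
        )
    (out_dir / "config_used.yaml").write_text(yaml.safe_dump(config.to_dict()))
    log.info("outputs written to %s", out_dir)

    return {
        "volume": vol,
        "truth": truth,
        "segmentation": seg,
        "records": records,
        "report": report,
        "metrics2d": metrics2d,
        "config_hash": chash,
    }


# ---------------------------------------------------------------------------
# Detection scoring
# ---------------------------------------------------------------------------


def score_detection(
    pred_labels: np.ndarray,
    truth_labels: np.ndarray,
    truth_subset: list[int] | None = None,
    min_overlap: float = 0.5,
) -> dict:
    """Object-level recall/precision of a predicted label map.

    A truth object is *matched* when a single predicted component covers at
    least ``min_overlap`` of its voxels; a predicted component is matched
    when a single truth object covers at least ``min_overlap`` of *its*
    voxels.  Recall runs over the truth objects (optionally a subset of
    truth labels, e.g. cracks only); precision over all predicted
    components, reported as None when there are none.
    """
    pred_labels = np.asarray(pred_labels)
    truth_labels = np.asarray(truth_labels)
    if pred_labels.shape != truth_labels.shape:
        raise ValueError(
            f"shape mismatch: {pred_labels.shape} vs {truth_labels.shape}"
        )
    t_ids = [int(t) for t in np.unique(truth_labels) if t != 0]
    if truth_subset is not None:
        t_ids = [t for t in t_ids if t in set(truth_subset)]
    p_ids = [int(p) for p in np.unique(pred_labels) if p != 0]

    # Joint histogram over (truth, pred) pairs on overlapping voxels.
    both = (truth_labels > 0) & (pred_labels > 0)
    pairs: dict[tuple[int, int], int] = {}
    if both.any():
        tv = truth_labels[both].astype(np.int64)
        pv = pred_labels[both].astype(np.int64)
        key = tv * (pred_labels.max() + 1) + pv
        uniq, cnt = np.unique(key, return_counts=True)
        for k, c in zip(uniq, cnt):
            pairs[(int(k // (pred_labels.max() + 1)), int(k % (pred_labels.max() + 1)))] = int(c)

    t_counts = np.bincount(truth_labels.ravel())
    p_counts = np.bincount(pred_labels.ravel())
    t_sizes = {t: int(t_counts[t]) for t in t_ids}
    p_sizes = {p: int(p_counts[p]) for p in p_ids}

    rows = []
    matched_t = 0
    for t in t_ids:
        best_p, best_c = 0, 0
        for (tt, pp), c in pairs.items():
            if tt == t and c > best_c:
                best_p, best_c = pp, c
        frac = best_c / t_sizes[t] if t_sizes[t] else 0.0
        ok = frac >= min_overlap
        matched_t += ok
        rows.append(
            {"truth": t, "pred": best_p, "overlap_frac": frac, "matched": bool(ok)}
        )

    matched_p = 0
    for p in p_ids:
        best_c = max((c for (tt, pp), c in pairs.items() if pp == p), default=0)
        if p_sizes[p] and best_c / p_sizes[p] >= min_overlap:
            matched_p += 1

    recall = matched_t / len(t_ids) if t_ids else float("nan")
    precision = matched_p / len(p_ids) if p_ids else None
    return {
        "recall": recall,
        "precision": precision,
        "n_truth": len(t_ids),
        "n_pred": len(p_ids),
        "per_object": rows,
    }
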