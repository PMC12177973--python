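"""End-to-end orchestration of the four cleaning stages.

Fixed stage order: marker detection -> restoration -> tissue detection ->
segregation.  The marker and restoration stages can be toggled off for
platforms without fiducial markers (e.g. Stereo-seq or Xenium rasters);
disabled stages pass their input through bit-unchanged.  Every enabled
stage writes its artifact to the output directory together with a manifest
recording inputs, configuration hash, seed and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from slideprep import io as sio
from slideprep.marker import MarkerSegmenter
from slideprep.metrics import MetricReport, evaluate_masks, iou as _iou
from slideprep.restore import Inpainter
from slideprep.segregate import SegregationConfig, segregate
from slideprep.synthetic import ConfigError
from slideprep.tissue import TissueDetectConfig, TissueDetector

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    detect_markers: bool = True
    restore: bool = True
    marker_checkpoint: str | None = None
    tissue_checkpoint: str | None = None
    external_marker_mask: str | None = None
    inpaint_backend: str = "biharmonic"
    tissue: TissueDetectConfig = field(default_factory=TissueDetectConfig)
    segregation: SegregationConfig = field(default_factory=SegregationConfig)
    seed: int = 0
    output_dir: str = "slideprep_out"

    def dump(self) -> dict:
        d = asdict(self)
        d["tissue"] = self.tissue.dump()
        d["segregation"] = self.segregation.dump()
        return d

    def validate(self):
        if self.restore and not self.detect_markers \
                and not self.external_marker_mask:
            raise ConfigError("restoration requires the marker stage or an "
                              "external marker mask")


@dataclass
class PipelineResult:
    marker_prob: np.ndarray | None = None
    marker_mask: np.ndarray | None = None
    restored: np.ndarray | None = None
    tissue_prob: np.ndarray | None = None
    tissue_blend: np.ndarray | None = None
    labeled_tissue: np.ndarray | None = None
    report: MetricReport | None = None
    timings: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _hash_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(image, cfg: PipelineConfig,
                 marker_model: MarkerSegmenter | None = None,
                 tissue_model: TissueDetector | None = None) -> PipelineResult:
    """Run the enabled stages over one slide image.

    ``image`` is a path or an RGB array.  Models may be passed directly or
    loaded from the checkpoints named in the config.  Intermediates are
    written to ``cfg.output_dir`` with a manifest; a stage failure stops
    the run, keeps partial outputs and records the failure point.
    """
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    img = sio.read_image(image) if isinstance(image, (str, Path)) else image
    result = PipelineResult()
    manifest = {
        "input": str(image) if isinstance(image, (str, Path)) else "array",
        "input_hash": _hash_array(img),
        "config": cfg.dump(),
        "seed": cfg.seed,
        "version": _version(),
        "stages": [],
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()).hexdigest()[:16]
    result.manifest = manifest
    current = img
    try:
        if cfg.detect_markers:
            t0 = time.perf_counter()
            if marker_model is None:
                if not cfg.marker_checkpoint:
                    raise ConfigError("marker stage enabled but no model or "
                                      "checkpoint given")
                marker_model = MarkerSegmenter.load(cfg.marker_checkpoint)
            result.marker_prob = marker_model.predict_proba(img)
            result.marker_mask = marker_model.predict(img)
            sio.write_mask(result.marker_prob, outdir / "marker_prob.tif")
            sio.write_mask(result.marker_mask, outdir / "marker_mask.png")
            result.timings["markers"] = time.perf_counter() - t0
            manifest["stages"].append("markers")
        elif cfg.external_marker_mask:
            result.marker_mask = sio.read_mask(cfg.external_marker_mask)

        if cfg.restore:
            t0 = time.perf_counter()
            inp = Inpainter(backend=cfg.inpaint_backend)
            result.restored = inp.inpaint_patched(current, result.marker_mask)
            sio.write_image(result.restored, outdir / "restored.png")
            current = result.restored
            result.timings["restore"] = time.perf_counter() - t0
            manifest["stages"].append("restore")

        t0 = time.perf_counter()
        if tissue_model is None:
            if not cfg.tissue_checkpoint:
                raise ConfigError("tissue stage requires a model or checkpoint")
            tissue_model = TissueDetector.load(cfg.tissue_checkpoint)
        tissue_model.config = cfg.tissue
        tres = tissue_model.detect(current)
        result.tissue_prob = tres.prob
        result.tissue_blend = tres.blend
        sio.write_mask(tres.prob, outdir / "tissue_prob.tif")
        sio.write_image(tres.blend, outdir / "tissue_blend.png")
        result.timings["tissue"] = time.perf_counter() - t0
        manifest["stages"].append("tissue")

        t0 = time.perf_counter()
        result.labeled_tissue = segregate(result.tissue_prob, cfg.segregation)
        sio.write_mask(result.labeled_tissue.astype(np.int32),
                       outdir / "tissue_labels.png")
        result.timings["segregate"] = time.perf_counter() - t0
        manifest["stages"].append("segregate")
    except Exception as exc:
        manifest["failure"] = {"stage_index": len(manifest["stages"]),
                               "error": str(exc)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    manifest["output_hashes"] = {
        name: _hash_array(arr) for name, arr in (
            ("marker_mask", result.marker_mask),
            ("restored", result.restored),
            ("tissue_prob", result.tissue_prob),
            ("labeled_tissue", result.labeled_tissue),
        ) if arr is not None
    }
    manifest["timings"] = result.timings
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


def evaluate_run(result: PipelineResult, marker_gold=None,
                 tissue_gold=None) -> MetricReport:
    """Score a pipeline run against gold-standard masks.

    Marker IoU is reported when both a marker prediction and its gold mask
    exist; tissue IoU/Hausdorff/perimeter-ratio/component-difference when
    tissue gold is given.  Missing gold leaves the metric absent.
    """
    report = MetricReport()
    if marker_gold is not None and result.marker_mask is not None:
        report.iou = _iou(result.marker_mask, marker_gold)
    if tissue_gold is not None and result.labeled_tissue is not None:
        tissue_pred = (result.labeled_tissue > 0).astype(np.uint8)
        tr = evaluate_masks(tissue_pred, tissue_gold)
        if report.iou is None:
            report.iou = tr.iou
        report.hausdorff = tr.hausdorff
        report.perim_ratio = tr.perim_ratio
        report.comp_diff = tr.comp_diff
    else:
        logger.info("no tissue gold provided; tissue metrics absent")
    result.report = report
    return report


def _version() -> str:
    from slideprep import __version__
    return __version__
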