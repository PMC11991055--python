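"""End-to-end runner: denoise → HSV → enhance(V) → segment → diagnose.

The stage order mirrors the acquisition-to-display workflow of the
diagnostic system the package models: impulse denoising on the RGB image,
conversion to HSV, contrast enhancement of the V plane only, three-stage
multidimensional segmentation of the characteristic lesion colors, and
rule-based quantification/classification.  Batch runs log and skip
per-image failures; single-image runs propagate errors.
"""

from __future__ import annotations

import csv
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import denoise as dn
from . import enhance as en
from . import diagnose as dg
from . import raster_core as rc
from . import segment as sg
from .config import PipelineConfig, dump_config

__all__ = ["StageOutputs", "process_image", "run_pipeline"]

log = logging.getLogger("lettucevision")


@dataclass
class StageOutputs:
    """Per-image result with the intermediate rasters of every stage."""

    report: dg.DeficiencyReport
    denoised: np.ndarray = field(repr=False, default=None)
    hsv: np.ndarray = field(repr=False, default=None)
    v_enhanced: np.ndarray = field(repr=False, default=None)
    mask: np.ndarray = field(repr=False, default=None)
    plant_mask: np.ndarray = field(repr=False, default=None)


def _enhance_v(v8: np.ndarray, config: PipelineConfig) -> np.ndarray:
    method = config.enhance.method
    if method == "ghe":
        return en.global_equalize(v8)
    if method == "clahe":
        return en.improved_clahe(v8, config.enhance.clahe_params())
    return en.clgce(v8, config.enhance.fusion_params())


def process_image(img: np.ndarray, config: PipelineConfig | None = None) -> StageOutputs:
    """Run the full pipeline on one 8-bit RGB image."""
    config = config or PipelineConfig()
    img = rc.validate_rgb(np.asarray(img))

    denoised = dn.dynamic_median_filter(img, config.denoise.theta)
    hsv = rc.rgb_to_hsv(denoised)

    v8 = np.clip(np.floor(hsv[:, :, 2] + 0.5), 0, 255).astype(np.uint8)
    v_enh = _enhance_v(v8, config)
    hsv_enh = hsv.copy()
    hsv_enh[:, :, 2] = v_enh

    plant = dg.plant_mask_from_hsv(
        hsv, config.diagnose.plant_sat_min, config.diagnose.plant_val_min
    )
    mask = sg.multidimensional_segment(
        hsv_enh,
        config.segment.hsv_bands(),
        config.segment.params(config.edges),
        roi=plant,
    )
    rules = config.diagnose.rules()
    ratio = dg.deficient_ratio(mask, plant)
    features = dg.color_features(hsv, mask, rules)
    report = dg.classify(features, ratio, rules)
    return StageOutputs(
        report=report,
        denoised=denoised,
        hsv=hsv,
        v_enhanced=v_enh,
        mask=mask,
        plant_mask=plant,
    )


def _persist(out_dir: str, stem: str, result: StageOutputs, save_intermediates: bool):
    report_path = os.path.join(out_dir, f"{stem}.report.json")
    with open(report_path, "w") as fh:
        json.dump(result.report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    if save_intermediates:
        rc.write_image(os.path.join(out_dir, f"{stem}.denoised.png"), result.denoised)
        rc.write_image(os.path.join(out_dir, f"{stem}.venhanced.png"), result.v_enhanced)
        rc.write_image(
            os.path.join(out_dir, f"{stem}.mask.png"),
            result.mask.astype(np.uint8) * 255,
        )


def run_pipeline(
    inputs: list,
    config: PipelineConfig | None = None,
    out_dir: str | None = None,
) -> list[dg.DeficiencyReport]:
    """Process a batch of images (paths or arrays); optionally persist results.

    When *out_dir* is given it receives one ``<stem>.report.json`` per
    image, a ``summary.csv``, the fully resolved ``config.yaml`` and a
    plain-text ``run.log``.  Returns the reports in input order; a failed
    image in a multi-image batch is logged and skipped (its slot is
    omitted from the summary), while a single-image run re-raises.
    """
    config = config or PipelineConfig()
    log.setLevel(getattr(logging, config.logging.level.upper(), logging.INFO))
    handlers = []
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        dump_config(config, os.path.join(out_dir, "config.yaml"))
        fh = logging.FileHandler(os.path.join(out_dir, "run.log"), mode="w")
        fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(fh)
        handlers.append(fh)

    reports: list[dg.DeficiencyReport] = []
    rows = []
    try:
        for i, item in enumerate(inputs):
            if isinstance(item, (str, os.PathLike)):
                stem = os.path.splitext(os.path.basename(os.fspath(item)))[0]
                loader = lambda it=item: rc.read_image(it)
            else:
                stem = f"image_{i:04d}"
                loader = lambda it=item: np.asarray(it)
            try:
                img = loader()
                result = process_image(img, config)
            except Exception as exc:
                if len(inputs) == 1:
                    raise
                log.error("skipping %s: %s", stem, exc)
                continue
            rep = result.report
            reports.append(rep)
            log.info(
                "%s: ratio=%.4f nutrient=%s severity=%s",
                stem, rep.ratio, rep.nutrient, rep.severity,
            )
            rows.append([stem, f"{rep.ratio:.6f}", rep.nutrient, rep.severity])
            if out_dir is not None:
                _persist(out_dir, stem, result, config.io.save_intermediates)
        if out_dir is not None:
            with open(os.path.join(out_dir, "summary.csv"), "w", newline="") as fh2:
                writer = csv.writer(fh2)
                writer.writerow(["image", "ratio", "nutrient", "severity"])
                writer.writerows(rows)
    finally:
        for h in handlers:
            log.removeHandler(h)
            h.close()
    return reports
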