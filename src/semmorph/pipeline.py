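"""End-to-end measurement pipeline and report rendering.

Chains the stages in the order the analysis runs on a micrograph:
denoise -> active-contour ROI -> fuzzy segmentation (whole frame) ->
progressive refinement -> connected-component labeling (foreground class
intersected with the ROI) -> per-object measurement -> size-class
grouping -> group summary tables. Everything is deterministic given the
config, so repeated runs produce byte-identical CSVs.

Foreground selection: the fuzzy classes are sorted by center intensity,
so "bright" foreground means the top class and "dark" the bottom one;
the class mask is intersected with the active-contour ROI before
labeling.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .denoise import WaveletSettings, wavelet_denoise
from .image import CalibratedImage
from .io import load_image
from .morphometry import (
    GroupSummary,
    ObjectRecord,
    classify_size_groups,
    label_objects,
    measure_body,
    measure_tube,
    round_half_away,
    summarize_group,
)
from .periodicity import LamellaeSettings, count_myelin_layers
from .segmentation import (
    ROI,
    active_contour_roi,
    fuzzy_cluster_segment,
    progressive_refine,
)

__all__ = ["PipelineError", "RunManifest", "run_pipeline", "render_summary_table"]

logger = logging.getLogger("semmorph")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and context."""


@dataclass
class RunManifest:
    """Snapshot of one run: config, versions, counts, warnings."""

    config: dict
    version: str
    n_images: int = 0
    n_objects: int = 0
    n_rejected: int = 0
    n_groups: int = 0
    warnings: list = field(default_factory=list)
    stage_parameters: dict = field(default_factory=dict)
    complete: bool = False
    outputs: dict = field(default_factory=dict)


_OBJECT_COLUMNS = [
    "image", "object_id", "kind", "area_um2", "feret_diameter_um",
    "equiv_diameter_um", "tube_diameter_nm", "wall_thickness_nm",
    "centroid_row", "centroid_col", "n_pixels", "n_boundary_pixels",
    "group_label",
]


def _measure_component(label_map: np.ndarray, object_id: int,
                       pixel_size: float) -> ObjectRecord:
    """Measure one component, deciding cell-body vs tube by elongation."""
    mask = label_map == object_id
    diameter_nm, widths, kind = measure_tube(mask, pixel_size)
    rec = measure_body(label_map, object_id, pixel_size)
    rec.object_id = int(object_id)
    if kind == "axon_tube":
        rec.kind = "axon_tube"
        rec.tube_diameter_nm = diameter_nm
    return rec


def _segment_and_measure(image: CalibratedImage, cfg: PipelineConfig,
                         manifest: RunManifest, name: str) -> list[ObjectRecord]:
    if cfg.denoise.enabled:
        settings = WaveletSettings(
            family=cfg.denoise.family,
            levels=cfg.denoise.levels,
            threshold_rule=cfg.denoise.threshold_rule,
            threshold_value=cfg.denoise.threshold_value,
            shrinkage=cfg.denoise.shrinkage,
        )
        image = wavelet_denoise(image, settings)
        logger.info("%s: denoised (%s, %d levels)", name, settings.family,
                    settings.levels)

    roi = active_contour_roi(image, max_iter=cfg.roi.max_iter,
                             smoothing=cfg.roi.smoothing)
    if roi.degenerate_contrast:
        manifest.warnings.append(f"{name}: degenerate contrast, ROI from init")
        logger.warning("%s: degenerate contrast", name)
    if roi.empty:
        manifest.warnings.append(f"{name}: empty ROI, no objects")
        return []

    labeling = fuzzy_cluster_segment(
        image, ROI.full(image.shape),
        n_classes=cfg.fuzzy.n_classes,
        fuzziness=cfg.fuzzy.fuzziness,
        tol=cfg.fuzzy.tol,
        max_iter=cfg.fuzzy.max_iter,
        features=cfg.fuzzy.features,
    )
    if cfg.refine.enabled:
        labeling = progressive_refine(
            labeling, image,
            ambiguity_threshold=cfg.refine.ambiguity_threshold,
            max_rounds=cfg.refine.max_rounds,
            fuzziness=cfg.fuzzy.fuzziness,
        )

    k = labeling.n_classes
    fg_classes = [k - 1] if cfg.morphometry.foreground == "bright" else [0]
    _, label_map, rejected = label_objects(
        labeling, fg_classes, min_area=cfg.morphometry.min_area_px,
        restrict_mask=roi.mask,
    )
    manifest.n_rejected += rejected
    if rejected:
        logger.info("%s: %d components below min_area rejected", name, rejected)

    records = []
    for oid in range(1, int(label_map.max()) + 1):
        rec = _measure_component(label_map, oid, image.pixel_size)
        records.append(rec)
    logger.info("%s: %d objects measured", name, len(records))
    return records


def run_pipeline(cfg: PipelineConfig,
                 images: list[CalibratedImage] | None = None) -> RunManifest:
    """Run the full measurement chain and write all outputs.

    ``images`` may be passed directly (e.g. from the simulator); otherwise
    the paths in the config are loaded. Outputs: objects.csv, groups.csv,
    summary.txt, optional lamellae.csv, manifest.json and a run log.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    manifest = RunManifest(config=cfg.to_dict(), version=__version__)
    try:
        if images is None:
            if not cfg.images:
                raise PipelineError("input: no images configured")
            images = [load_image(p, cfg.pixel_size_nm) for p in cfg.images]
        if not images:
            raise PipelineError("input: no images to process")
        manifest.n_images = len(images)

        all_records: list[tuple[str, ObjectRecord]] = []
        for i, img in enumerate(images):
            name = img.source_id or f"image_{i}"
            try:
                recs = _segment_and_measure(img, cfg, manifest, name)
            except Exception as exc:  # noqa: BLE001 - stage context re-raise
                raise PipelineError(f"segment/measure[{name}]: {exc}") from exc
            all_records.extend((name, r) for r in recs)
        manifest.n_objects = len(all_records)

        # size-class grouping over cell bodies
        bodies = [(n, r) for n, r in all_records if r.kind == "cell_body"]
        summaries: list[GroupSummary] = []
        if len(bodies) >= cfg.morphometry.n_groups and cfg.morphometry.n_groups >= 1:
            diams = [r.feret_diameter_um for _, r in bodies]
            labels = classify_size_groups(diams, k=cfg.morphometry.n_groups)
            for (_, rec), lab in zip(bodies, labels):
                rec.group_label = str(lab)
            for lab in sorted(set(labels)):
                sel = [r for (_, r), l in zip(bodies, labels) if l == lab]
                dmean, dsd, dsem = summarize_group(
                    [r.feret_diameter_um for r in sel])
                amean, asd, asem = summarize_group([r.area_um2 for r in sel])
                summaries.append(GroupSummary(
                    group_label=str(lab), n=len(sel),
                    mean_diameter_um=dmean, sd_diameter_um=dsd,
                    sem_diameter_um=dsem, mean_area_um2=amean,
                    sd_area_um2=asd, sem_area_um2=asem,
                ))
        manifest.n_groups = len(summaries)

        # write objects.csv
        rows = []
        for name, r in all_records:
            rows.append({
                "image": name, "object_id": r.object_id, "kind": r.kind,
                "area_um2": r.area_um2,
                "feret_diameter_um": r.feret_diameter_um,
                "equiv_diameter_um": r.equiv_diameter_um,
                "tube_diameter_nm": r.tube_diameter_nm,
                "wall_thickness_nm": r.wall_thickness_nm,
                "centroid_row": r.centroid[0] if r.centroid else None,
                "centroid_col": r.centroid[1] if r.centroid else None,
                "n_pixels": r.n_pixels,
                "n_boundary_pixels": r.n_boundary_pixels,
                "group_label": r.group_label,
            })
        objects_df = pd.DataFrame(rows, columns=_OBJECT_COLUMNS)
        objects_path = outdir / "objects.csv"
        objects_df.to_csv(objects_path, index=False)
        manifest.outputs["objects"] = str(objects_path)

        groups_df = pd.DataFrame([dataclasses.asdict(s) for s in summaries])
        groups_path = outdir / "groups.csv"
        groups_df.to_csv(groups_path, index=False)
        manifest.outputs["groups"] = str(groups_path)

        summary_path = outdir / "summary.txt"
        summary_path.write_text(render_summary_table(
            summaries,
            diameter_decimals=cfg.report.diameter_decimals,
            area_decimals=cfg.report.area_decimals,
        ))
        manifest.outputs["summary"] = str(summary_path)

        # optional lamellae analysis per image, on the active-contour ROI
        if cfg.periodicity.enabled:
            lam_rows = []
            settings = LamellaeSettings(
                period_min_nm=cfg.periodicity.period_min_nm,
                period_max_nm=cfg.periodicity.period_max_nm,
                n_angles=cfg.periodicity.n_angles,
            )
            for i, img in enumerate(images):
                name = img.source_id or f"image_{i}"
                try:
                    roi = active_contour_roi(img, max_iter=cfg.roi.max_iter,
                                             smoothing=cfg.roi.smoothing)
                    res = count_myelin_layers(img, roi, settings)
                    lam_rows.append({
                        "image": name,
                        "n_layers": res.n_layers,
                        "period_nm": res.period_nm,
                        "period_defined": res.period_defined,
                        "confidence": res.confidence,
                    })
                except Exception as exc:  # noqa: BLE001
                    manifest.warnings.append(f"lamellae[{name}]: {exc}")
            lam_path = outdir / "lamellae.csv"
            pd.DataFrame(
                lam_rows,
                columns=["image", "n_layers", "period_nm", "period_defined",
                         "confidence"],
            ).to_csv(lam_path, index=False)
            manifest.outputs["lamellae"] = str(lam_path)

        manifest.complete = True
    finally:
        manifest.stage_parameters = cfg.to_dict()
        (outdir / "manifest.json").write_text(
            json.dumps(dataclasses.asdict(manifest), indent=2, default=str))
        logger.removeHandler(handler)
        handler.close()
    return manifest


def render_summary_table(
    summaries: list[GroupSummary],
    diameter_decimals: int = 2,
    sem_decimals: int = 3,
    area_decimals: int = 1,
    precision: dict | None = None,
) -> str:
    """Plain-text group table: one column per class, mean ± SEM rows.

    ``precision`` optionally overrides decimals per group label, e.g.
    ``{"1B": {"diameter": 2, "diameter_sem": 2}}`` — published tables
    often print each class at its own precision.
    """
    precision = precision or {}
    header = ["", *(f"{s.group_label} (mean ± SEM)" for s in summaries)]
    lines = ["\t".join(header)]

    def nd_for(label, key, default):
        return precision.get(label, {}).get(key, default)

    def fmt(mean, sem, nd, nd_sem):
        if mean is None:
            return ""
        mtxt = f"{round_half_away(mean, nd):.{max(nd, 0)}f}"
        if sem is None:
            return mtxt
        return f"{mtxt} ± {round_half_away(sem, nd_sem):.{max(nd_sem, 0)}f}"

    row_d = ["diameter (um)"] + [
        fmt(s.mean_diameter_um, s.sem_diameter_um,
            nd_for(s.group_label, "diameter", diameter_decimals),
            nd_for(s.group_label, "diameter_sem", sem_decimals))
        for s in summaries
    ]
    row_a = ["mean area (um^2)"] + [
        fmt(s.mean_area_um2, s.sem_area_um2,
            nd_for(s.group_label, "area", area_decimals),
            nd_for(s.group_label, "area_sem", sem_decimals))
        for s in summaries
    ]
    row_n = ["n"] + [str(s.n) for s in summaries]
    lines += ["\t".join(row_d), "\t".join(row_a), "\t".join(row_n)]
    return "\n".join(lines) + "\n"
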