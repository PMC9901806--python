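"""Single-image and batch processing pipelines with atomic CSV output."""

from __future__ import annotations

import logging
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import cell_events as ce
from . import features as ft
from . import tracking as tr
from .curve_tracer import trace_filaments
from .preprocessing import apply_pipeline, binarize, load_stack
from .sensing import compute_width_map, scan_straight_filaments
from .settings import Settings
from .viz import save_overlay

log = logging.getLogger("filatrack")

IMAGE_SUFFIXES = (".tif", ".tiff", ".png")

__all__ = ["run_single", "run_batch", "detect_frame"]


def _atomic_write_csv(df: pd.DataFrame, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            df.to_csv(fh, index=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def detect_frame(gray: np.ndarray, settings: Settings):
    """Filter, binarize and trace one frame; returns (filaments, records, mask)."""
    filtered = apply_pipeline(gray, settings.filter_pipeline())
    mask = binarize(
        filtered, settings.binarization_method, **settings.binarization_params
    )
    if settings.mode == "straight":
        wm = compute_width_map(mask, settings.sensor.tolerance)
        filaments, _ = scan_straight_filaments(wm, settings.sensor)
    else:
        filaments = trace_filaments(mask, settings.tracer)
    records = [ft.filament_descriptors(f, gray) for f in filaments]
    return filaments, records, mask


def run_single(path, settings: Settings, outdir) -> dict:
    """Process one image or stack; writes filament/summary/cell CSVs and,
    for stacks, tracking and cell-event CSVs.  All writes are atomic."""
    path = Path(path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = path.stem
    stack = load_stack(path)
    frames_filaments, frames_records = [], []
    fil_rows, summary_rows, cell_rows = [], [], []
    for t, gray in enumerate(stack):
        filaments, records, mask = detect_frame(gray, settings)
        frames_filaments.append(filaments)
        frames_records.append(records)
        log.info("%s frame %d: %d filaments", path.name, t, len(filaments))
        for r in records:
            row = {"frame": t}
            row.update(r.as_dict())
            fil_rows.append(row)
        summary = {"frame": t}
        summary.update(ft.frame_summary(records))
        summary_rows.append(summary)
        if mask.any():
            cell = ft.cell_shape_descriptors(mask, gray)
            crow = {"frame": t}
            crow.update(cell.as_dict())
            cell_rows.append(crow)
        if settings.export.overlays:
            save_overlay(gray, filaments, outdir / f"{stem}_overlay_{t:03d}.png")

    fil_cols = ["frame", "id", "center_x", "center_y", "length", "width", "angle", "curvature"]
    _atomic_write_csv(pd.DataFrame(fil_rows, columns=fil_cols), outdir / f"{stem}_filaments.csv")
    _atomic_write_csv(pd.DataFrame(summary_rows), outdir / f"{stem}_summary.csv")
    cell_cols = ["frame", "area", "center_x", "center_y", "long_half_axis",
                 "short_half_axis", "aspect_ratio", "mean_brightness"]
    _atomic_write_csv(pd.DataFrame(cell_rows, columns=cell_cols), outdir / f"{stem}_cells.csv")

    result = {
        "path": str(path),
        "frames": len(stack),
        "filaments": sum(len(fs) for fs in frames_filaments),
    }
    if len(stack) > 1:
        lifelines = tr.track_stack(
            frames_filaments,
            settings.tracking,
            min_persistence=settings.export.min_persistence,
            max_persistence=settings.export.max_persistence,
        )
        layouts = (
            ("frame", "id")
            if settings.export.tracking_layout == "both"
            else (settings.export.tracking_layout,)
        )
        for layout in layouts:
            df = tr.tracking_table(lifelines, frames_records, layout=layout)
            _atomic_write_csv(df, outdir / f"{stem}_tracking_by_{layout}.csv")
        result["lifelines"] = len(lifelines)

        frames_areas = [
            ce.detect_areas(
                binarize(
                    apply_pipeline(g, settings.filter_pipeline()),
                    settings.binarization_method,
                    **settings.binarization_params,
                ),
                min_area=settings.cell_events.min_area,
                frame=t,
            )
            for t, g in enumerate(stack)
        ]
        if any(frames_areas):
            mmap = ce.build_matching_map(frames_areas)
            lls, evs = ce.classify_events(
                frames_areas, mmap, settings.cell_events.intersect_tolerance
            )
            lls, evs = ce.postprocess_lifelines(lls, evs, frames_areas)
            _atomic_write_csv(ce.events_table(evs), outdir / f"{stem}_events.csv")
            _atomic_write_csv(ce.lifelines_table(lls), outdir / f"{stem}_lifelines.csv")
            result["events"] = len(evs)
    return result


def run_batch(root, settings: Settings) -> list:
    """Recurse sub-folders of ``root`` in lexicographic order and process
    every image within; one failing folder does not abort the rest."""
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(str(root))
    subfolders = sorted(
        p for p in root.rglob("*") if p.is_dir()
        and any(c.suffix.lower() in IMAGE_SUFFIXES for c in p.iterdir())
    )
    if not subfolders and any(c.suffix.lower() in IMAGE_SUFFIXES for c in root.iterdir()):
        subfolders = [root]
    report = []
    for folder in subfolders:
        images = sorted(
            c for c in folder.iterdir() if c.suffix.lower() in IMAGE_SUFFIXES
        )
        status, detail = "OK", ""
        for img in images:
            try:
                run_single(img, settings, folder)
            except Exception as e:  # noqa: BLE001 - per-folder isolation
                status, detail = "FAILED", f"{img.name}: {e}"
                log.error("batch failure in %s: %s", folder, detail)
                break
        report.append({"folder": str(folder), "status": status, "detail": detail})
        log.info("batch %s: %s", folder, status)
    return report
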