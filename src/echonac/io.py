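"""Readers and writers binding the pipeline stages together.

Images are 16-bit grayscale PNG (intensities in [0,1] scaled to 0..65535);
masks are 8-bit PNG with {0,255}; cohort manifests and measurement tables
are CSV; metric reports are JSON; run configuration is YAML.  Writers
round-trip through readers (masks losslessly; images up to 16-bit
quantization).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .geometry import TumorMeasurements
from .phantom import CohortRecord, UltrasoundImage

MANIFEST_COLUMNS = ["patient_id", "cycle", "image_path", "mask_path",
                    "px_per_cm", "true_area_cm2", "pcr_label"]


def write_image(image: UltrasoundImage, path) -> None:
    arr = np.round(image.pixels * 65535).astype(np.uint16)
    Image.fromarray(arr).save(path)


def read_image(path, px_per_cm: float) -> UltrasoundImage:
    arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a grayscale image, got shape {arr.shape}")
    scale = 65535.0 if arr.dtype == np.uint16 else 255.0
    return UltrasoundImage(arr.astype(np.float64) / scale, px_per_cm)


def write_mask(mask: np.ndarray, path) -> None:
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(arr, mode="L").save(path)


def read_mask(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr > 127).astype(np.uint8)


def write_cohort(cohort: list[CohortRecord], directory,
                 write_images: bool = True) -> Path:
    """Write per-cycle PNGs plus a manifest CSV; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    meas_rows = []
    for rec in cohort:
        for c in range(rec.n_cycles + 1):
            img_path = mask_path = ""
            px_per_cm = np.nan
            if write_images and rec.images is not None:
                img_path = f"{rec.patient_id}_c{c}.png"
                mask_path = f"{rec.patient_id}_c{c}_mask.png"
                write_image(rec.images[c], directory / img_path)
                write_mask(rec.masks[c], directory / mask_path)
                px_per_cm = rec.images[c].px_per_cm
            rows.append({"patient_id": rec.patient_id, "cycle": c,
                         "image_path": img_path, "mask_path": mask_path,
                         "px_per_cm": px_per_cm,
                         "true_area_cm2": rec.true_areas[c],
                         "pcr_label": int(rec.pcr_label)})
            meas_rows.append({"patient_id": rec.patient_id, "cycle": c,
                              **{m: rec.measurements[m][c] for m in rec.measurements}})
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    pd.DataFrame(meas_rows).to_csv(directory / "measurements.csv", index=False)
    return manifest


def read_cohort(manifest_path) -> list[CohortRecord]:
    """Rebuild cohort records (measurements + labels) from manifest CSVs.

    Requires a ``measurements.csv`` beside the manifest; raises a validation
    error naming the file if a patient lacks a cycle-0 (pre-NAC) row.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{manifest_path}: missing columns {missing}")
    meas_path = manifest_path.parent / "measurements.csv"
    meas = pd.read_csv(meas_path) if meas_path.exists() else None
    records = []
    for pid, sub in df.groupby("patient_id", sort=True):
        sub = sub.sort_values("cycle")
        if sub["cycle"].min() != 0:
            raise ValueError(f"{manifest_path}: patient {pid} lacks a pre-NAC "
                             "(cycle 0) row")
        cycles = sub["cycle"].to_numpy()
        if not np.array_equal(cycles, np.arange(len(cycles))):
            raise ValueError(f"{manifest_path}: patient {pid} has non-contiguous cycles")
        true_areas = sub["true_area_cm2"].to_numpy(dtype=float)
        measurements = {}
        if meas is not None:
            msub = meas[meas["patient_id"] == pid].sort_values("cycle")
            for col in msub.columns:
                if col not in ("patient_id", "cycle"):
                    measurements[col] = msub[col].to_numpy(dtype=float)
        n = len(true_areas)
        records.append(CohortRecord(
            patient_id=str(pid), pcr_label=bool(sub["pcr_label"].iloc[0]),
            true_areas=true_areas, semi_axes_cm=np.zeros((n, 2)),
            orientation=0.0, measurements=measurements))
    return records


def write_measurements(table: list[tuple[str, TumorMeasurements]], path) -> None:
    rows = [{"image": name, **asdict(m)} for name, m in table]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_metric_report(report: dict, path) -> None:
    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    Path(path).write_text(json.dumps(_clean(report), indent=2))


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_config(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))
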