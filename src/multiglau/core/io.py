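"""File I/O: tabular CSV, image bundles on disk, and JSON metric reports.

On-disk image layout is one file per modality per sample:
``<sample_id>_global.png``, ``<sample_id>_focused.png``,
``<sample_id>_rnfl.png`` (``.tif`` also accepted).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .types import MODALITIES, ClinicalRecord, Dataset, ImageBundle, SeverityStage

__all__ = [
    "read_tabular",
    "write_tabular",
    "read_bundle",
    "write_bundle",
    "write_metrics",
    "read_metrics",
    "save_dataset",
    "load_dataset",
]

_REQUIRED_COLUMNS = ("sample_id", "age", "gender", "bcva", "iop", "cdr")
_OPTIONAL_COLUMNS = ("md", "glaucoma_label", "stage_label")


class TabularFormatError(ValueError):
    """Malformed header or non-parsable cell in a clinical CSV."""


def _parse_float(value, column: str, row: int) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise TabularFormatError(
            f"row {row}: cannot parse {column}={value!r} as a number"
        ) from None


def read_tabular(path) -> list[ClinicalRecord]:
    """Read clinical records from CSV (RFC-4180, UTF-8, header row).

    Empty cells denote missing values and are kept as explicit absences.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TabularFormatError(f"{path}: header missing column(s) {missing_cols}")

    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        gender = row.get("gender") or None
        stage = row.get("stage_label") or None
        glab = row.get("glaucoma_label") or None
        records.append(
            ClinicalRecord(
                sample_id=str(row["sample_id"]),
                age=_parse_float(row.get("age"), "age", i),
                gender=gender,
                bcva=_parse_float(row.get("bcva"), "bcva", i),
                iop=_parse_float(row.get("iop"), "iop", i),
                cdr=_parse_float(row.get("cdr"), "cdr", i),
                md=_parse_float(row.get("md"), "md", i) if "md" in row else None,
                glaucoma_label=None if glab is None else int(glab),
                stage_label=None if stage is None else SeverityStage.from_name(stage),
            )
        )
    return records


def write_tabular(records: Iterable[ClinicalRecord], path) -> None:
    """Write records to CSV; ``read_tabular`` round-trips cell-for-cell."""
    rows = []
    for r in records:
        rows.append({
            "sample_id": r.sample_id,
            "age": r.age,
            "gender": r.gender,
            "bcva": r.bcva,
            "iop": r.iop,
            "cdr": r.cdr,
            "md": r.md,
            "glaucoma_label": r.glaucoma_label,
            "stage_label": None if r.stage_label is None else str(r.stage_label),
        })
    df = pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS) + list(_OPTIONAL_COLUMNS))
    df.to_csv(path, index=False, float_format="%.10g")


def _bundle_path(directory: Path, sample_id: str, modality: str) -> Optional[Path]:
    for ext in (".png", ".tif", ".tiff"):
        p = directory / f"{sample_id}_{modality}{ext}"
        if p.exists():
            return p
    return None


def read_bundle(directory, sample_id: str, mask: Sequence[bool]) -> ImageBundle:
    """Load the image modalities flagged True in ``mask`` for one sample.

    Raises ``FileNotFoundError`` if a requested modality file is absent.
    Pixel values are kept on their native scale.
    """
    directory = Path(directory)
    if len(mask) != 3:
        raise ValueError("mask must have 3 entries (global, focused, rnfl)")
    bundle = ImageBundle()
    for want, modality in zip(mask, MODALITIES):
        if not want:
            continue
        p = _bundle_path(directory, sample_id, modality)
        if p is None:
            raise FileNotFoundError(
                f"no {modality} image for sample {sample_id!r} in {directory}"
            )
        try:
            with Image.open(p) as im:
                arr = np.asarray(im)
        except Exception as exc:  # unreadable / corrupt file
            raise ValueError(f"cannot decode image {p}: {exc}") from exc
        bundle.set(modality, arr)
    return bundle


def write_bundle(bundle: ImageBundle, directory, sample_id: str) -> list[Path]:
    """Write each present raster as ``<sample_id>_<modality>.png`` (uint8)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for modality in MODALITIES:
        img = bundle.get(modality)
        if img is None:
            continue
        arr = np.asarray(img)
        if arr.dtype != np.uint8:
            lo, hi = float(arr.min()), float(arr.max())
            scaled = np.zeros_like(arr, dtype=float) if hi == lo else (arr - lo) / (hi - lo)
            arr = (scaled * 255).round().astype(np.uint8)
        p = directory / f"{sample_id}_{modality}.png"
        Image.fromarray(arr).save(p)
        written.append(p)
    return written


def write_metrics(report: dict, path) -> None:
    """Write a metric report as JSON; values must be finite numbers or nested dicts."""

    def _check(obj, keypath=""):
        if isinstance(obj, dict):
            for k, v in obj.items():
                _check(v, f"{keypath}.{k}")
        elif isinstance(obj, (list, tuple)):
            for i, v in enumerate(obj):
                _check(v, f"{keypath}[{i}]")
        elif isinstance(obj, (int, float, np.integer, np.floating)):
            if not math.isfinite(float(obj)):
                raise ValueError(f"non-finite metric value at {keypath or '<root>'}")
        elif not isinstance(obj, (str, bool, type(None))):
            raise TypeError(f"unsupported metric type {type(obj)} at {keypath}")

    _check(report)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def read_metrics(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def save_dataset(ds: Dataset, directory, write_images: bool = True) -> None:
    """Persist a dataset: records.csv, presence.csv, and image files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_tabular(ds.records, directory / "records.csv")
    presence = pd.DataFrame(
        [dict(zip(MODALITIES, b.presence), sample_id=r.sample_id)
         for r, b in zip(ds.records, ds.bundles)],
        columns=["sample_id", *MODALITIES],
    )
    presence.to_csv(directory / "presence.csv", index=False)
    if write_images:
        img_dir = directory / "images"
        for r, b in zip(ds.records, ds.bundles):
            write_bundle(b, img_dir, r.sample_id)


def load_dataset(directory, load_images: bool = True) -> Dataset:
    directory = Path(directory)
    records = read_tabular(directory / "records.csv")
    presence = pd.read_csv(directory / "presence.csv")
    presence = presence.set_index("sample_id")
    bundles = []
    for r in records:
        mask = [bool(presence.loc[r.sample_id, m]) for m in MODALITIES]
        if load_images and any(mask):
            bundles.append(read_bundle(directory / "images", r.sample_id, mask))
        else:
            bundles.append(ImageBundle())
    return Dataset(records=records, bundles=bundles)
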