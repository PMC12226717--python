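"""Shared domain types for the three-tier glaucoma diagnosis toolkit.

One sample is one eye-visit.  The five screening features (age, gender,
BCVA, IOP, CDR) are cheap clinical measurements; the optional MD value
(mean deviation of the visual field, dB) drives severity labels; up to
three image modalities (global fundus, polar-transformed "focused"
fundus, RNFL thickness map) accompany each record.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "SeverityStage",
    "ClinicalRecord",
    "ImageBundle",
    "Dataset",
    "FeatureMap",
    "MODALITIES",
    "FEATURE_ORDER",
    "GENDER_ENCODING",
]

#: Image modality names, in canonical order (aligned with presence masks).
MODALITIES = ("global", "focused", "rnfl")

#: Screening feature names, in the order every model consumes them.
FEATURE_ORDER = ("age", "gender", "bcva", "iop", "cdr")

#: Gender is encoded female -> 0, male -> 1 throughout.
GENDER_ENCODING = {"female": 0.0, "male": 1.0}


class SeverityStage(enum.IntEnum):
    """Four-class visual-field damage severity, ordered from mild to worst."""

    EARLY = 0
    MODERATE = 1
    ADVANCED = 2
    SEVERE = 3

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name.lower()

    @classmethod
    def from_name(cls, name: str) -> "SeverityStage":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown severity stage {name!r}") from None


@dataclass
class ClinicalRecord:
    """One eye-visit's tabular data.

    ``bcva`` is accepted as a raw numeric visual-acuity value; no
    decimal/logMAR conversion is applied (the scale is whatever the
    source table uses — document it alongside your data).
    Missing numeric measurements are ``None``, never 0.
    """

    sample_id: str
    age: Optional[float] = None
    gender: Optional[str] = None  # "female" | "male"
    bcva: Optional[float] = None
    iop: Optional[float] = None
    cdr: Optional[float] = None
    md: Optional[float] = None
    glaucoma_label: Optional[int] = None
    stage_label: Optional[SeverityStage] = None

    def __post_init__(self) -> None:
        if self.age is not None and not (0.0 < self.age <= 120.0):
            raise ValueError(f"{self.sample_id}: age {self.age} outside (0, 120]")
        if self.cdr is not None and not (0.0 <= self.cdr <= 1.0):
            raise ValueError(f"{self.sample_id}: cdr {self.cdr} outside [0, 1]")
        if self.iop is not None and self.iop <= 0:
            raise ValueError(f"{self.sample_id}: iop {self.iop} must be > 0")
        if self.bcva is not None and self.bcva < 0:
            raise ValueError(f"{self.sample_id}: bcva {self.bcva} must be >= 0")
        if self.gender is not None and self.gender not in GENDER_ENCODING:
            raise ValueError(f"{self.sample_id}: gender {self.gender!r} not in {set(GENDER_ENCODING)}")
        if self.md is not None and not math.isfinite(self.md):
            raise ValueError(f"{self.sample_id}: md must be finite")

    def feature_vector(self) -> np.ndarray:
        """The 5 screening features as floats (NaN where missing)."""
        vals = []
        for name in FEATURE_ORDER:
            v = getattr(self, name)
            if name == "gender":
                v = GENDER_ENCODING[v] if v is not None else None
            vals.append(np.nan if v is None else float(v))
        return np.asarray(vals, dtype=float)

    def missing_features(self) -> list[str]:
        return [n for n, v in zip(FEATURE_ORDER, self.feature_vector()) if np.isnan(v)]


@dataclass
class ImageBundle:
    """Up to three image modalities for one eye, with a presence mask.

    ``presence[i]`` is False exactly when the corresponding raster is
    absent (``None``).  Order follows :data:`MODALITIES`.
    """

    global_img: Optional[np.ndarray] = None
    focused_img: Optional[np.ndarray] = None
    rnfl_img: Optional[np.ndarray] = None

    @property
    def presence(self) -> tuple[bool, bool, bool]:
        return (self.global_img is not None,
                self.focused_img is not None,
                self.rnfl_img is not None)

    def get(self, modality: str) -> Optional[np.ndarray]:
        if modality not in MODALITIES:
            raise KeyError(f"unknown modality {modality!r}")
        return getattr(self, f"{modality}_img")

    def set(self, modality: str, img: Optional[np.ndarray]) -> None:
        if modality not in MODALITIES:
            raise KeyError(f"unknown modality {modality!r}")
        setattr(self, f"{modality}_img", img)

    def drop_images(self) -> "ImageBundle":
        """A copy with every raster absent (presence all False)."""
        return ImageBundle()

    def copy(self) -> "ImageBundle":
        return ImageBundle(
            global_img=None if self.global_img is None else self.global_img.copy(),
            focused_img=None if self.focused_img is None else self.focused_img.copy(),
            rnfl_img=None if self.rnfl_img is None else self.rnfl_img.copy(),
        )


@dataclass
class Dataset:
    """Aligned records and image bundles, one pair per eye-visit."""

    records: list[ClinicalRecord] = field(default_factory=list)
    bundles: list[ImageBundle] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.records) != len(self.bundles):
            raise ValueError(
                f"records ({len(self.records)}) and bundles ({len(self.bundles)}) "
                "have different lengths"
            )
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[ClinicalRecord, ImageBundle]]:
        return iter(zip(self.records, self.bundles))

    def subset(self, indices: Sequence[int]) -> "Dataset":
        return Dataset(
            records=[self.records[i] for i in indices],
            bundles=[self.bundles[i] for i in indices],
            metadata=dict(self.metadata),
        )

    def feature_matrix(self) -> np.ndarray:
        """n x 5 matrix of screening features (NaN marks missing cells)."""
        return np.stack([r.feature_vector() for r in self.records])

    def labels(self, which: str = "glaucoma") -> np.ndarray:
        if which == "glaucoma":
            vals = [r.glaucoma_label for r in self.records]
        elif which == "stage":
            vals = [None if r.stage_label is None else int(r.stage_label)
                    for r in self.records]
        else:
            raise ValueError(f"unknown label kind {which!r}")
        if any(v is None for v in vals):
            raise ValueError(f"{which} label missing for some samples")
        return np.asarray(vals, dtype=int)


@dataclass
class FeatureMap:
    """A (channels, height, width) activation array flowing through blocks."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"feature map must be (C, H, W), got {self.values.shape}")
        if min(self.values.shape) < 1:
            raise ValueError("C, H, W must all be >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature map contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape
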