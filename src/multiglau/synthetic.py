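"""Synthetic glaucoma cohorts: tabular features, phantom images, labels.

The generator emulates the class-conditional structure of a real
referral cohort: per-stage mean age (58.0 / 62.5 / 62.4 / 61.4 years)
and mean IOP (18.64 / 20.88 / 22.71 / 25.79 mmHg) rise with
visual-field severity, CDR rises and BCVA falls stochastically with
stage, and the severe group has a reduced female fraction (~44.86%).
MD is drawn uniformly inside each stage's interval (severe truncated
at -35 dB), so stage labels are always derivable from MD.

Images are geometric phantoms, not photorealistic fundus pictures: a
disc/cup phantom whose cup-to-disc diameter ratio equals the record's
CDR, its polar transform about the disc centre ("focused" view), and
an RNFL-style band image whose mean intensity decreases with severity
in proportion to ``signal_strength``.  Only these monotone relations
are contractual.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .core.types import ClinicalRecord, Dataset, ImageBundle, SeverityStage
from .staging import DEFAULT_RULE, StagingRule, stage_from_md

__all__ = [
    "CohortSpec",
    "MissingnessSpec",
    "generate_cohort",
    "generate_images",
    "inject_missingness",
    "STAGE_MEAN_AGE",
    "STAGE_MEAN_IOP",
]

#: Per-stage population means the generator reproduces (early..severe).
STAGE_MEAN_AGE = (58.0, 62.5, 62.4, 61.4)      # years
STAGE_MEAN_IOP = (18.64, 20.88, 22.71, 25.79)  # mmHg
STAGE_FEMALE_FRACTION = (0.55, 0.55, 0.55, 0.4486)
STAGE_MEAN_CDR = (0.55, 0.65, 0.75, 0.85)
STAGE_MEAN_BCVA = (0.70, 0.55, 0.40, 0.25)

#: Stage class prior, proportional to the 1198/655/535/1157 cohort counts.
DEFAULT_CLASS_PROBS = (1198 / 3545, 655 / 3545, 535 / 3545, 1157 / 3545)

_MD_FLOOR = -35.0  # dB, truncation of the severe stage interval


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n: int = 400
    class_probs: tuple = DEFAULT_CLASS_PROBS
    healthy_fraction: float = 0.5
    seed: int = 0
    image_size: int = 64
    signal_strength: float = 1.0
    age_sd: float = 8.0
    iop_sd: float = 2.5
    cdr_sd: float = 0.07
    bcva_sd: float = 0.12

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        p = np.asarray(self.class_probs, dtype=float)
        if p.shape != (4,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("class_probs must be 4 nonnegative reals summing to 1")
        if not 0.0 <= self.healthy_fraction <= 1.0:
            raise ValueError("healthy_fraction must be in [0, 1]")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be nonnegative")
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")


@dataclass(frozen=True)
class MissingnessSpec:
    """Completely-at-random image missingness conditions."""

    rate: float
    n_replicates: int = 10
    joint_image_drop: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rate must be in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _stage_md_interval(stage: int, rule: StagingRule) -> tuple[float, float]:
    # half-open conventions match stage_from_md; endpoints nudged inward
    if stage == int(SeverityStage.EARLY):
        return rule.cut_early, 2.0
    if stage == int(SeverityStage.MODERATE):
        return rule.cut_moderate, rule.cut_early - 1e-6
    if stage == int(SeverityStage.ADVANCED):
        return rule.cut_advanced + 1e-6, rule.cut_moderate - 1e-6
    return _MD_FLOOR, rule.cut_advanced


def generate_cohort(spec: CohortSpec, with_images: bool = True,
                    rule: StagingRule = DEFAULT_RULE) -> Dataset:
    """Generate one cohort; a pure function of ``spec`` (incl. its seed).

    Glaucomatous samples draw a stage from ``class_probs`` and an MD
    uniformly inside that stage's interval; healthy samples carry no MD
    and have lower CDR/IOP.  Every generated stage label satisfies
    ``stage_from_md(md) == stage_label``.
    """
    rng = np.random.default_rng(spec.seed)
    n_healthy = int(round(spec.n * spec.healthy_fraction))
    records: list[ClinicalRecord] = []

    for i in range(spec.n):
        sid = f"s{i:05d}"
        healthy = i < n_healthy
        if healthy:
            age = float(np.clip(rng.normal(55.0, 10.0), 20.0, 95.0))
            iop = float(np.clip(rng.normal(15.5, spec.iop_sd), 6.0, 60.0))
            cdr = float(np.clip(rng.normal(0.35, 0.08), 0.05, 0.95))
            bcva = float(np.clip(rng.normal(0.90, 0.10), 0.0, 1.5))
            gender = "female" if rng.random() < 0.55 else "male"
            records.append(ClinicalRecord(
                sample_id=sid, age=age, gender=gender, bcva=bcva, iop=iop,
                cdr=cdr, md=None, glaucoma_label=0, stage_label=None,
            ))
        else:
            stage = int(rng.choice(4, p=np.asarray(spec.class_probs)))
            lo, hi = _stage_md_interval(stage, rule)
            md = float(rng.uniform(lo, hi))
            age = float(np.clip(rng.normal(STAGE_MEAN_AGE[stage], spec.age_sd), 20.0, 95.0))
            iop = float(np.clip(rng.normal(STAGE_MEAN_IOP[stage], spec.iop_sd), 6.0, 60.0))
            cdr = float(np.clip(rng.normal(STAGE_MEAN_CDR[stage], spec.cdr_sd), 0.05, 1.0))
            bcva = float(np.clip(rng.normal(STAGE_MEAN_BCVA[stage], spec.bcva_sd), 0.0, 1.5))
            gender = "female" if rng.random() < STAGE_FEMALE_FRACTION[stage] else "male"
            stage_label = stage_from_md(md, rule)
            assert int(stage_label) == stage
            records.append(ClinicalRecord(
                sample_id=sid, age=age, gender=gender, bcva=bcva, iop=iop,
                cdr=cdr, md=md, glaucoma_label=1, stage_label=stage_label,
            ))

    if with_images:
        bundles = [generate_images(r, spec) for r in records]
    else:
        bundles = [ImageBundle() for _ in records]
    return Dataset(records=records, bundles=bundles,
                   metadata={"spec": spec.__dict__.copy()})


def _record_rng(spec_seed: int, sample_id: str) -> np.random.Generator:
    # stable per-sample stream: seed sequence from (cohort seed, crc32 of id)
    return np.random.default_rng([spec_seed, zlib.crc32(sample_id.encode())])


def disc_geometry(image_size: int) -> tuple[tuple[float, float], float]:
    """Disc centre (row, col) and disc radius used by the phantom."""
    c = (image_size - 1) / 2.0
    return (c, c), 0.30 * image_size


def generate_images(record: ClinicalRecord, spec: CohortSpec) -> ImageBundle:
    """Phantom image bundle for one record; deterministic given seed and id.

    - ``global_img``: textured background with a bright disc ellipse and a
      brighter cup whose diameter ratio to the disc equals ``record.cdr``.
    - ``focused_img``: polar transform of the global phantom about the
      disc centre (disc magnified into the low-radius rows).
    - ``rnfl_img``: horizontal band image; mean intensity decreases with
      severity level in proportion to ``signal_strength``.
    All rasters are float64 in [0, 1], ``image_size`` square.
    """
    if record.stage_label is None and record.glaucoma_label is None:
        raise ValueError(f"{record.sample_id}: need stage_label or glaucoma_label")
    from .preprocessing import PolarSpec, polar_transform  # local: avoid cycle at import time

    rng = _record_rng(spec.seed, record.sample_id)
    size = spec.image_size
    (cr, cc), disc_r = disc_geometry(size)
    rows, cols = np.mgrid[0:size, 0:size].astype(float)

    # -- global phantom ------------------------------------------------
    background = 0.35 + 0.04 * rng.standard_normal((size, size))
    # mild vessel-like sinusoidal texture
    background += 0.03 * np.sin(2 * np.pi * rows / size * 3.0 + rng.uniform(0, 2 * np.pi))
    dist = np.hypot(rows - cr, cols - cc)
    img = background.copy()
    img[dist <= disc_r] = 0.60 + 0.02 * rng.standard_normal(int((dist <= disc_r).sum()))
    cdr = 0.3 if record.cdr is None else record.cdr
    cup_r = np.clip(cdr + rng.normal(0.0, 0.01), 0.0, 1.0) * disc_r
    if cup_r > 0:
        img[dist <= cup_r] = 0.90 + 0.02 * rng.standard_normal(int((dist <= cup_r).sum()))
    global_img = np.clip(img, 0.0, 1.0)

    # -- focused phantom: polar view magnifying the disc ---------------
    pspec = PolarSpec(center=(cr, cc), radius=1.6 * disc_r, output_size=(size, size))
    focused_img = polar_transform(global_img, pspec)

    # -- RNFL band phantom ---------------------------------------------
    if record.stage_label is not None:
        level = float(int(record.stage_label) + 1)  # early=1 .. severe=4
    else:
        level = 0.0 if record.glaucoma_label == 0 else 1.0
    base = 0.85 - 0.12 * spec.signal_strength * level  # mean falls with severity
    band = base + 0.10 * np.cos(2 * np.pi * cols / size)  # arcuate-bundle-like bands
    band = band + 0.05 * rng.standard_normal((size, size))
    rnfl_img = np.clip(band, 0.0, 1.0)

    return ImageBundle(global_img=global_img, focused_img=focused_img,
                       rnfl_img=rnfl_img)


def inject_missingness(ds: Dataset, spec: MissingnessSpec) -> list[Dataset]:
    """Apply MCAR image missingness; returns ``n_replicates`` datasets.

    With ``joint_image_drop`` a single Bernoulli(rate) draw per sample
    removes all three image modalities together (tabular features stay);
    otherwise each modality is dropped independently at ``rate``.
    """
    if not all(all(b.presence) for b in ds.bundles):
        raise ValueError("input dataset must be complete (all modalities present)")
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n_replicates):
        bundles = []
        for b in ds.bundles:
            if spec.joint_image_drop:
                bundles.append(ImageBundle() if rng.random() < spec.rate else b.copy())
            else:
                nb = b.copy()
                for modality in ("global", "focused", "rnfl"):
                    if rng.random() < spec.rate:
                        nb.set(modality, None)
                bundles.append(nb)
        out.append(Dataset(records=list(ds.records), bundles=bundles,
                           metadata={**ds.metadata, "missing_rate": spec.rate}))
    return out
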