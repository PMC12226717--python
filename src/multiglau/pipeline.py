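"""End-to-end three-tier pipeline orchestration.

Runs simulate -> preprocess -> screening train/eval -> missingness
replicates with pre-diagnosis train/eval per rate -> definitive
diagnosis train/eval -> saliency, writing per-stage metric files and a
manifest sufficient to re-run bit-identically from one seed.  Every
stochastic stage derives its seed from the single top-level seed.

The screening tier touches only the tabular features — it never reads
image files — mirroring the design point that tier 1 must work where
imaging is unavailable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .core.io import save_dataset, write_metrics
from .core.types import Dataset
from .evaluation import roc_auc, multiclass_auc, multiclass_metrics
from .fusion import FreezeMissingClassifier, M3VFClassifier, prediag_labels
from .preprocessing import preprocess_bundle
from .saliency import gradcam_pp, guided_backprop, overlay
from .screening import ScreeningClassifier, explain_shap, select_operating_point
from .synthetic import CohortSpec, MissingnessSpec, generate_cohort, inject_missingness

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("multiglau")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, manifest: dict):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class RunConfig:
    out_dir: str = "multiglau_run"
    seed: int = 0
    n: int = 400
    healthy_fraction: float = 0.5
    image_size: int = 32
    signal_strength: float = 1.0
    missing_rates: tuple = (0.0, 0.2, 0.4)
    screening_kind: str = "xgb"
    hpo_budget: int = 8
    widths: tuple = (8, 12, 16)
    embed_dim: int = 32
    epochs: int = 6
    lr: float = 1e-3
    test_fraction: float = 0.25
    log_level: str = "INFO"

    def stage_seed(self, stage: str) -> int:
        # stable per-stage stream derived from the single top-level seed
        import zlib
        return (self.seed * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


def _split(n: int, test_fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = max(1, int(round(n * test_fraction)))
    return perm[n_test:], perm[:n_test]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every tier at the configured scale; returns the manifest."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in cfg.__dict__.items()},
                      "stages": {}, "metrics_files": []}
    stage = "simulate"
    try:
        log.info("simulate: n=%d", cfg.n)
        spec = CohortSpec(n=cfg.n, healthy_fraction=cfg.healthy_fraction,
                          seed=cfg.stage_seed("simulate"),
                          image_size=cfg.image_size,
                          signal_strength=cfg.signal_strength)
        cohort = generate_cohort(spec)
        save_dataset(cohort, out / "data", write_images=False)
        manifest["stages"]["simulate"] = {"n": cfg.n, "seed": spec.seed,
                                          "out": str(out / "data")}

        stage = "preprocess"
        log.info("preprocess: normalizing image stacks")
        bundles = [preprocess_bundle(b, size=cfg.image_size) for b in cohort.bundles]
        cohort = Dataset(records=cohort.records, bundles=bundles,
                         metadata=cohort.metadata)
        manifest["stages"]["preprocess"] = {"size": cfg.image_size}

        stage = "screen"
        log.info("screen: %s with hpo_budget=%d", cfg.screening_kind, cfg.hpo_budget)
        tr, te = _split(len(cohort), cfg.test_fraction, cfg.stage_seed("screen"))
        # tier isolation: the screening tier sees tabular features only
        X, y = cohort.feature_matrix(), cohort.labels("glaucoma")
        scr = ScreeningClassifier(kind=cfg.screening_kind, hpo_budget=cfg.hpo_budget,
                                  seed=cfg.stage_seed("screen"))
        scr.fit(X[tr], y[tr])
        p = scr.predict_proba(X[te])[:, 1]
        roc = roc_auc(p, y[te])
        op = select_operating_point(p, y[te], 0.85, "target_sensitivity")
        shap_report = explain_shap(scr, X[te][:32])
        screen_metrics = {
            "auc": roc.auc,
            "cv_auc": scr.cv_auc_,
            "operating_point": {"threshold": op.threshold,
                                "sensitivity": op.achieved_sensitivity,
                                "specificity": op.achieved_specificity},
            "shap_ranking": shap_report.ranking,
        }
        write_metrics(screen_metrics, out / "screen_metrics.json")
        manifest["stages"]["screen"] = screen_metrics
        manifest["metrics_files"].append(str(out / "screen_metrics.json"))

        stage = "prediag"
        glauc_idx = [i for i, r in enumerate(cohort.records) if r.stage_label is not None]
        glauc = cohort.subset(glauc_idx)
        tr, te = _split(len(glauc), cfg.test_fraction, cfg.stage_seed("prediag"))
        prediag_metrics = {}
        for rate in cfg.missing_rates:
            log.info("prediag: missing rate %.2f", rate)
            mspec = MissingnessSpec(rate=rate, n_replicates=1,
                                    seed=cfg.stage_seed(f"prediag-{rate}"))
            injected = inject_missingness(glauc, mspec)[0]
            fm = FreezeMissingClassifier(
                widths=cfg.widths, image_size=cfg.image_size, lr=cfg.lr,
                epochs=cfg.epochs, seed=cfg.stage_seed("prediag"))
            fm.fit(injected.subset(tr))
            p = fm.predict_proba(injected.subset(te))[:, 1]
            prediag_metrics[f"rate_{rate:g}"] = {
                "auc": roc_auc(p, prediag_labels(injected.subset(te))).auc}
        write_metrics(prediag_metrics, out / "prediag_metrics.json")
        manifest["stages"]["prediag"] = prediag_metrics
        manifest["metrics_files"].append(str(out / "prediag_metrics.json"))

        stage = "diag"
        log.info("diag: m3vf on %d glaucomatous samples", len(glauc))
        m3 = M3VFClassifier(widths=cfg.widths, embed_dim=cfg.embed_dim,
                            n_heads=2, image_size=cfg.image_size, lr=cfg.lr,
                            epochs=cfg.epochs, seed=cfg.stage_seed("diag"))
        m3.fit(glauc.subset(tr))
        proba = m3.predict_proba(glauc.subset(te))
        truth = glauc.subset(te).labels("stage")
        mm = multiclass_metrics(np.argmax(proba, axis=1), truth)
        diag_metrics = {"macro_auc": multiclass_auc(proba, truth),
                        "accuracy": mm["accuracy"],
                        "macro_sensitivity": mm["macro_sensitivity"],
                        "macro_specificity": mm["macro_specificity"]}
        write_metrics(diag_metrics, out / "diag_metrics.json")
        manifest["stages"]["diag"] = diag_metrics
        manifest["metrics_files"].append(str(out / "diag_metrics.json"))

        stage = "explain"
        log.info("explain: saliency maps for one test sample")
        i = int(te[0])
        rec, bun = glauc.records[i], glauc.bundles[i]
        target = int(rec.stage_label)
        region = gradcam_pp(m3.net_, bun, rec, target, modality="rnfl",
                            mean=m3.mean_, std=m3.std_)
        pixel = guided_backprop(m3.net_, bun, rec, target, modality="rnfl",
                                mean=m3.mean_, std=m3.std_)
        combo = overlay(region, pixel)
        sal_dir = out / "saliency"
        sal_dir.mkdir(exist_ok=True)
        for name, sal in [("region", region), ("pixel", pixel), ("overlay", combo)]:
            Image.fromarray((sal.heatmap * 255).astype(np.uint8)).save(
                sal_dir / f"{rec.sample_id}_{name}.png")
            np.savetxt(sal_dir / f"{rec.sample_id}_{name}.csv", sal.heatmap,
                       delimiter=",")
        manifest["stages"]["explain"] = {"sample": rec.sample_id,
                                         "target_class": target,
                                         "out": str(sal_dir)}
    except Exception as exc:
        raise PipelineError(stage, exc, manifest) from exc

    write_metrics({k: v for k, v in manifest.items() if k != "metrics_files"}
                  | {"metrics_files": manifest["metrics_files"]},
                  out / "manifest.json")
    return manifest
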