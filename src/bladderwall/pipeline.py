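"""End-to-end orchestration: phantom cohort -> segmentation -> features ->
selection -> classification -> evaluation, with every artifact written to a
run directory in plain formats (PNG masks, CSV tables/contours, JSON
results and config snapshot)."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import classification as clf
from . import feature_selection as fsel
from . import imaging, seg_metrics
from .config import PipelineConfig
from .gwo import GWOConfig
from .levelset_seg import LevelSetParams, SegmentationConfig, segment_wall
from .phantom import PhantomSample, PhantomSpec, generate_cohort
from .preprocess import ContrastConfig
from .wall_features import FeatureConfig, WallRegion, extract_all

log = logging.getLogger("bladderwall")

__all__ = ["cohort_specs", "segmentation_config", "feature_config",
           "segment_sample", "extract_sample", "run_pipeline"]


def cohort_specs(cfg: PipelineConfig) -> tuple[PhantomSpec, PhantomSpec]:
    common = dict(
        image_size=cfg["phantom.image_size"],
        pixel_spacing=cfg["phantom.pixel_spacing"],
        base_inner_radius=cfg["phantom.inner_radius"],
        noise_sigma=cfg["phantom.noise_sigma"],
    )
    spec0 = PhantomSpec(
        wall_thickness_mean=cfg["phantom.class0.thickness_mean"],
        wall_thickness_sd=cfg["phantom.class0.thickness_sd"],
        irregularity_amplitude=cfg["phantom.class0.irregularity"],
        n_diverticula=cfg["phantom.class0.n_diverticula"],
        label=0, **common,
    )
    spec1 = PhantomSpec(
        wall_thickness_mean=cfg["phantom.class1.thickness_mean"],
        wall_thickness_sd=cfg["phantom.class1.thickness_sd"],
        irregularity_amplitude=cfg["phantom.class1.irregularity"],
        n_diverticula=cfg["phantom.class1.n_diverticula"],
        label=1, **common,
    )
    return spec0, spec1


def segmentation_config(cfg: PipelineConfig) -> SegmentationConfig:
    shared = dict(
        dt=cfg["ls.dt"], gaussian_sigma=cfg["ls.sigma"], edge_scale=cfg["ls.edge_scale"],
        edge_weight=cfg["ls.alpha"], curvature_weight=cfg["ls.beta"],
        stop_tol=cfg["ls.stop_tol"], reinit_every=cfg["ls.reinit_every"],
    )
    return SegmentationConfig(
        smooth_radius=cfg["smooth.radius"],
        contrast=ContrastConfig(window=cfg["contrast.window"]),
        inner=LevelSetParams(max_iters=cfg["ls.inner_max_iters"],
                             balloon=cfg["ls.inner_balloon"], **shared),
        outer=LevelSetParams(max_iters=cfg["ls.outer_max_iters"],
                             balloon=cfg["ls.outer_balloon"], **shared),
        max_thickness_mm=cfg["outer.max_thickness_mm"],
        min_separation_px=cfg["outer.min_separation_px"],
    )


def feature_config(cfg: PipelineConfig) -> FeatureConfig:
    return FeatureConfig(glcm_levels=cfg["glcm.levels"], n_theta=cfg["polar.n_theta"])


def segment_sample(sample: PhantomSample, seg_cfg: SegmentationConfig,
                   seed_radius: float = 5.0):
    spec = sample.spec
    n = spec.image_size
    center = spec.center or ((n - 1) / 2.0, (n - 1) / 2.0)
    return segment_wall(sample.image, center, seed_radius=seed_radius, config=seg_cfg)


def extract_sample(sample: PhantomSample, seg, feat_cfg: FeatureConfig) -> np.ndarray:
    region = WallRegion(
        image=sample.image, wall_mask=seg.wall_mask,
        inner_contour=seg.inner_contour, outer_contour=seg.outer_contour,
        outer_mask=seg.outer_mask,
    )
    return extract_all(region, feat_cfg)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> Path:
    """Run the whole workflow, returning the populated run directory."""
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    (out / "contours").mkdir(exist_ok=True)
    cfg.to_json(out / "config.json")

    logging.basicConfig(level=logging.INFO)
    seed = cfg["seed"]
    log.info("run seed = %d", seed)

    spec0, spec1 = cohort_specs(cfg)
    samples = generate_cohort(cfg["phantom.n_per_class"], spec0, spec1, seed=seed)
    seg_cfg = segmentation_config(cfg)
    feat_cfg = feature_config(cfg)

    ids, vectors, labels, seg_scores = [], [], [], []
    for i, sample in enumerate(samples):
        sid = f"img{i:03d}"
        try:
            seg = segment_sample(sample, seg_cfg, cfg["seed_disk.radius_px"])
            vec = extract_sample(sample, seg, feat_cfg)
        except Exception as exc:
            raise RuntimeError(f"stage failure on {sid}: {exc}") from exc
        imaging.write_image(sample.image, out / "masks" / f"{sid}.png")
        imaging.write_mask(seg.wall_mask, out / "masks" / f"{sid}_wall.png")
        imaging.write_contour(seg.inner_contour, out / "contours" / f"{sid}_inner.csv")
        imaging.write_contour(seg.outer_contour, out / "contours" / f"{sid}_outer.csv")
        seg_scores.append(seg_metrics.evaluate_masks(sample.wall_mask, seg.wall_mask))
        ids.append(sid)
        vectors.append(vec)
        labels.append(sample.label)
    table = imaging.feature_table(ids, vectors, labels)
    imaging.write_feature_table(table, out / "features.csv")

    (out / "segmentation_metrics.json").write_text(json.dumps({
        "per_image": seg_scores,
        "mean_dice": float(np.mean([s["dice"] for s in seg_scores])),
        "mean_mi_bits": float(np.mean([s["mi_bits"] for s in seg_scores])),
        "mean_overall_error": float(np.mean([s["overall_error"] for s in seg_scores])),
    }, indent=2) + "\n")

    X = np.vstack(vectors)
    y = np.where(np.asarray(labels) == 1, 1, -1)
    data = clf.Dataset(X, y, tuple(ids))

    # feature selection scored by CV accuracy of the RBF SVM
    objective = clf.cv_accuracy_objective(
        data, clf.ClassifierConfig(kind="svm", kernel="rbf", C=1.0, gamma=1.0),
        k=cfg["cv.folds"], seed=seed,
    )
    sel_cfg = fsel.SelectionConfig(n_features=X.shape[1],
                                   floating=cfg["select.floating"],
                                   max_size=cfg["select.max_size"])
    method = fsel.sffs if cfg["select.method"] == "sffs" else fsel.sbfs
    selection = method(objective, sel_cfg)
    (out / "selection.json").write_text(json.dumps({
        "method": cfg["select.method"],
        "selected": list(selection.selected),
        "names": [imaging.FEATURE_NAMES[i] for i in selection.selected],
        "best_score": selection.best_score,
        "history": [[list(s), sc] for s, sc in selection.history],
    }, indent=2) + "\n")

    selected = clf.Dataset(X[:, list(selection.selected)], y, tuple(ids))
    gwo_cfg = GWOConfig(
        pack_size=cfg["gwo.pack_size"], iterations=cfg["gwo.iterations"],
        bounds=(tuple(cfg["gwo.log10C_bounds"]), tuple(cfg["gwo.log10gamma_bounds"])),
        seed=seed,
    )
    tuned = clf.gwo_svm(selected, gwo_cfg, k=cfg["cv.folds"], cv_seed=seed)
    svm_cfg = clf.ClassifierConfig(kind="svm", kernel="rbf", C=tuned.C, gamma=tuned.gamma)
    svm_held, svm_cv = clf.train_test_protocol(selected, svm_cfg,
                                               test_frac=cfg["cv.test_frac"], seed=seed)
    rf_cfg = clf.ClassifierConfig(kind="rf", seed=seed)
    rf_held, rf_cv = clf.train_test_protocol(selected, rf_cfg,
                                             test_frac=cfg["cv.test_frac"], seed=seed)

    (out / "metrics.json").write_text(json.dumps({
        "gwo_svm": {
            "C": tuned.C, "gamma": tuned.gamma,
            "cv": svm_cv.as_dict(), "held_out": svm_held.as_dict(),
            "trace": [float(v) for v in tuned.trace],
        },
        "random_forest": {"cv": rf_cv.as_dict(), "held_out": rf_held.as_dict()},
        "seed": seed,
    }, indent=2) + "\n")
    return out
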