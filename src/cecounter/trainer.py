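"""Supervised training with validation-loss epoch selection, plus the
two-stage semi-supervised workflow (initial model -> pseudo-labels ->
simulated manual correction -> cell count model).

The recorded train loss is a post-epoch evaluation pass (same estimator as
the validation loss), so identical train/val sets yield identical curves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .dataset_io import AnnotatedImage
from .detection import DetectionConfig, DetectionResult, extract_centers
from .evaluator import (
    DensityCorrelation,
    MatchResult,
    MetricsReport,
    compute_metrics,
    density_correlation,
    match_points,
)
from .preprocess import augment
from .quantify import FieldGeometry, density_from_centers
from .unet import Adam, LabelMask, UNet, UNetConfig, rasterize_labels

#: train:val proportions printed for the two stages (402:121 and 2341:757)
STAGE1_SPLIT = (402, 121)
STAGE2_SPLIT = (2341, 757)


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 30
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 4
    crop_size: int = 64
    seed: int = 0
    fg_weight: float = 1.0
    disk_radius_px: int = 3
    steps_per_epoch: int | None = None
    eval_max_images: int | None = None

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batch_size < 1 or self.crop_size < 1:
            raise ValueError("batch_size and crop_size must be >= 1")


@dataclass
class LossCurve:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.val_loss)


@dataclass(frozen=True)
class CorrectionPolicy:
    p_fix_miss: float = 1.0
    p_fix_spurious: float = 1.0
    jitter_px: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_fix_miss <= 1.0 or not 0.0 <= self.p_fix_spurious <= 1.0:
            raise ValueError("correction probabilities must be in [0, 1]")
        if self.jitter_px < 0:
            raise ValueError("jitter_px must be >= 0")


@dataclass
class TrainResult:
    best_params: dict[str, np.ndarray]
    curve: LossCurve
    best_epoch: int  # 1-based


# ---------------------------------------------------------------------------
# data plumbing


class _Samples:
    """Normalized images + rasterized masks, ready for cropping."""

    def __init__(self, records: Sequence[AnnotatedImage], disk_radius_px: int):
        self.images = [np.asarray(r.pixels, dtype=np.float32) / 255.0 for r in records]
        self.masks = [
            rasterize_labels(r.centers, r.pixels.shape, disk_radius_px).mask for r in records
        ]

    def __len__(self) -> int:
        return len(self.images)

    def crop(self, i: int, size: int, rng: np.random.Generator):
        img, mask = self.images[i], self.masks[i]
        h, w = img.shape
        if h < size or w < size:
            ph, pw = max(0, size - h), max(0, size - w)
            img = np.pad(img, ((0, ph), (0, pw)))
            mask = np.pad(mask, ((0, ph), (0, pw)))
            h, w = img.shape
        y0 = int(rng.integers(0, h - size + 1))
        x0 = int(rng.integers(0, w - size + 1))
        return img[y0 : y0 + size, x0 : x0 + size], mask[y0 : y0 + size, x0 : x0 + size]


def _pad_to_multiple(arr: np.ndarray, f: int, mode="reflect") -> np.ndarray:
    h, w = arr.shape
    ph, pw = (-h) % f, (-w) % f
    if ph or pw:
        arr = np.pad(arr, ((0, ph), (0, pw)), mode=mode)
    return arr


def evaluate_loss(
    model: UNet,
    samples: "_Samples",
    cfg: TrainConfig,
    subset: np.ndarray | None = None,
) -> float:
    """Mean full-image weighted cross-entropy over (a subset of) the samples."""
    weights = (1.0, cfg.fg_weight)
    f = model.cfg.down_factor
    idxs = range(len(samples)) if subset is None else subset
    losses = []
    for i in idxs:
        img = _pad_to_multiple(samples.images[i], f)
        mask = _pad_to_multiple(samples.masks[i], f, mode="constant")
        losses.append(model.loss(img[None, None], mask[None].astype(np.int64), weights))
    return float(np.mean(losses))


# ---------------------------------------------------------------------------
# operations


def train(
    model: UNet,
    train_set: Sequence[AnnotatedImage],
    val_set: Sequence[AnnotatedImage],
    cfg: TrainConfig,
) -> TrainResult:
    """Adam + weighted cross-entropy on random crops; returns the weights of
    the epoch with the lowest validation loss (earlier epoch wins ties)."""
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and val sets must be nonempty")
    d = model.cfg.down_factor
    crop = cfg.crop_size - (cfg.crop_size % d) or d
    rng = np.random.default_rng(cfg.seed)
    tr = _Samples(train_set, cfg.disk_radius_px)
    va = _Samples(val_set, cfg.disk_radius_px)
    tr_eval_subset = _eval_subset(len(tr), cfg, rng)
    va_eval_subset = _eval_subset(len(va), cfg, rng)
    opt = Adam(model.params, lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2)
    weights = (1.0, cfg.fg_weight)
    curve = LossCurve()
    best_val = math.inf
    best_params = model.get_params()
    best_epoch = 0
    steps = cfg.steps_per_epoch or max(1, math.ceil(len(tr) / cfg.batch_size))
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(tr))
        pos = 0
        for _ in range(steps):
            xs, ys = [], []
            for _ in range(cfg.batch_size):
                if pos >= len(order):
                    order = rng.permutation(len(tr))
                    pos = 0
                img, mask = tr.crop(int(order[pos]), crop, rng)
                pos += 1
                xs.append(img)
                ys.append(mask)
            x = np.stack(xs)[:, None]
            y = np.stack(ys).astype(np.int64)
            loss, grads = model.loss_and_grads(x, y, weights)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss ({loss}) at epoch {epoch}; "
                    "lower the learning rate or check the inputs"
                )
            opt.step(model.params, grads)
        curve.train_loss.append(evaluate_loss(model, tr, cfg, tr_eval_subset))
        val_loss = evaluate_loss(model, va, cfg, va_eval_subset)
        curve.val_loss.append(val_loss)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        if val_loss < best_val:
            best_val = val_loss
            best_params = model.get_params()
            best_epoch = epoch
    model.set_params(best_params)
    return TrainResult(best_params=best_params, curve=curve, best_epoch=best_epoch)


def _eval_subset(n: int, cfg: TrainConfig, rng: np.random.Generator):
    if cfg.eval_max_images is None or n <= cfg.eval_max_images:
        return None
    return rng.choice(n, size=cfg.eval_max_images, replace=False)


def select_epoch(curve: LossCurve) -> int:
    """1-based argmin of the validation loss; ties go to the earlier epoch."""
    if curve.n_epochs == 0:
        raise ValueError("empty loss curve")
    return int(np.argmin(curve.val_loss)) + 1


def pseudo_label(
    model: UNet,
    records: Sequence[AnnotatedImage],
    detect_cfg: DetectionConfig = DetectionConfig(),
) -> list[AnnotatedImage]:
    """Run detection on each image and emit model-sourced annotations."""
    out = []
    for rec in records:
        pmap = model.predict_proba(rec.pixels, image_id=rec.image_id)
        det = extract_centers(pmap, detect_cfg)
        out.append(rec.with_(centers=det.centers, source="model"))
    return out


def simulate_correction(
    pseudo: AnnotatedImage,
    truth: AnnotatedImage,
    policy: CorrectionPolicy,
    match_radius_px: float,
    rng: np.random.Generator | int = 0,
) -> AnnotatedImage:
    """Simulate the manual revision of pseudo-labels against ground truth.

    Matched predictions are kept as predicted; each missed true center is
    added with probability ``p_fix_miss`` (plus Gaussian jitter); each
    spurious prediction is removed with probability ``p_fix_spurious``.
    """
    if pseudo.image_id != truth.image_id:
        raise ValueError(
            f"image id mismatch: {pseudo.image_id!r} vs {truth.image_id!r}"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    m = match_points(pseudo.centers, truth.centers, match_radius_px, pseudo.image_id)
    matched_pred = {pi for pi, _, _ in m.pairs}
    matched_ref = {ri for _, ri, _ in m.pairs}
    kept = [pseudo.centers[pi] for pi in sorted(matched_pred)]
    for pi in range(len(pseudo.centers)):
        if pi in matched_pred:
            continue
        if rng.random() >= policy.p_fix_spurious:
            kept.append(pseudo.centers[pi])
    h, w = truth.pixels.shape if truth.pixels is not None else pseudo.pixels.shape
    for ri in range(len(truth.centers)):
        if ri in matched_ref:
            continue
        if rng.random() < policy.p_fix_miss:
            pt = truth.centers[ri].copy()
            if policy.jitter_px > 0:
                pt = pt + rng.normal(0.0, policy.jitter_px, size=2)
                pt[0] = np.clip(pt[0], 0, w - 1)
                pt[1] = np.clip(pt[1], 0, h - 1)
            kept.append(pt)
    centers = np.asarray(kept, dtype=np.float64).reshape(-1, 2)
    return pseudo.with_(centers=centers, source="model_corrected")


# ---------------------------------------------------------------------------
# two-stage semi-supervised workflow


@dataclass
class StageResult:
    params: dict[str, np.ndarray]
    curve: LossCurve
    selected_epoch: int
    metrics: MetricsReport
    density_corr: DensityCorrelation | None
    detections: list[DetectionResult]


@dataclass
class SemiSupervisedResult:
    initial: StageResult
    cellcount: StageResult


def _proportional_split(n: int, proportions: tuple[int, int], rng) -> tuple[np.ndarray, np.ndarray]:
    n_train = max(1, min(n - 1, int(round(n * proportions[0] / sum(proportions)))))
    perm = rng.permutation(n)
    return perm[:n_train], perm[n_train:]


def evaluate_model(
    model: UNet,
    test_set: Sequence[AnnotatedImage],
    detect_cfg: DetectionConfig,
    match_radius_px: float,
    bootstrap_reps: int = 2000,
    seed: int = 0,
) -> tuple[MetricsReport, DensityCorrelation | None, list[DetectionResult]]:
    """Detect on every test image, match against truth, report metrics and
    the predicted-vs-true density correlation."""
    matches: list[MatchResult] = []
    detections: list[DetectionResult] = []
    pred_d, true_d = [], []
    for rec in test_set:
        pmap = model.predict_proba(rec.pixels, image_id=rec.image_id)
        det = extract_centers(pmap, detect_cfg)
        detections.append(det)
        matches.append(match_points(det.centers, rec.centers, match_radius_px, rec.image_id))
        geom = FieldGeometry(rec.width, rec.height, rec.um_per_px)
        pred_d.append(density_from_centers(det, geom).density_cells_per_mm2)
        true_d.append(rec.n_centers / geom.field_area_mm2)
    report = compute_metrics(matches, bootstrap_reps=bootstrap_reps, seed=seed)
    corr = None
    if len(pred_d) >= 3 and np.std(pred_d) > 0 and np.std(true_d) > 0:
        corr = density_correlation(pred_d, true_d)
    return report, corr, detections


def run_semi_supervised(
    labeled: Sequence[AnnotatedImage],
    unlabeled: Sequence[AnnotatedImage],
    test: Sequence[AnnotatedImage],
    model_cfg: UNetConfig,
    train_cfg: TrainConfig,
    detect_cfg: DetectionConfig = DetectionConfig(),
    policy: CorrectionPolicy = CorrectionPolicy(),
    match_radius_px: float = 10.0,
    bootstrap_reps: int = 2000,
) -> SemiSupervisedResult:
    """Stage 1: train on the labeled pool (x2_flip) -> initial model.
    Stage 2: pseudo-label the unlabeled pool, simulate correction, merge,
    re-split, augment x4_flip, retrain -> cell count model. Both models are
    evaluated on the held-out test pool.

    ``unlabeled`` records carry their true centers, which are used only by
    the simulated correction step (standing in for the human reviser).
    """
    seed = train_cfg.seed
    rng = np.random.default_rng(seed)

    # stage 1 ---------------------------------------------------------------
    idx_tr, idx_va = _proportional_split(len(labeled), STAGE1_SPLIT, rng)
    train1 = augment([labeled[i] for i in idx_tr], "x2_flip")
    val1 = [labeled[i] for i in idx_va]
    model1 = UNet(replace(model_cfg, seed=seed))
    res1 = train(model1, train1, val1, replace(train_cfg, seed=seed + 1))
    metrics1, corr1, det1 = evaluate_model(
        model1, test, detect_cfg, match_radius_px, bootstrap_reps, seed
    )
    stage1 = StageResult(
        params=res1.best_params,
        curve=res1.curve,
        selected_epoch=select_epoch(res1.curve),
        metrics=metrics1,
        density_corr=corr1,
        detections=det1,
    )

    # stage 2 ---------------------------------------------------------------
    if len(unlabeled) == 0:
        warnings.warn("empty unlabeled pool: stage 2 degenerates to supervised training")
        corrected: list[AnnotatedImage] = []
    else:
        pseudo = pseudo_label(model1, unlabeled, detect_cfg)
        corr_rng = np.random.default_rng(seed + 2)
        corrected = [
            simulate_correction(ps, tr_, policy, match_radius_px, corr_rng)
            for ps, tr_ in zip(pseudo, unlabeled)
        ]
    pool = list(labeled) + corrected
    idx_tr2, idx_va2 = _proportional_split(len(pool), STAGE2_SPLIT, np.random.default_rng(seed + 3))
    train2 = augment([pool[i] for i in idx_tr2], "x4_flip")
    val2 = [pool[i] for i in idx_va2]
    model2 = UNet(replace(model_cfg, seed=seed))
    res2 = train(model2, train2, val2, replace(train_cfg, seed=seed + 4))
    metrics2, corr2, det2 = evaluate_model(
        model2, test, detect_cfg, match_radius_px, bootstrap_reps, seed
    )
    stage2 = StageResult(
        params=res2.best_params,
        curve=res2.curve,
        selected_epoch=select_epoch(res2.curve),
        metrics=metrics2,
        density_corr=corr2,
        detections=det2,
    )
    return SemiSupervisedResult(initial=stage1, cellcount=stage2)
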