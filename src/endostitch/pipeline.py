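"""Two-phase training, end-to-end stitching, outcome classification and
evaluation reports.

Training follows a two-phase schedule: the homography network is pre-trained
on a 128-pixel augmented dataset and then fine-tuned at 512 pixels (the
network is fully convolutional, so the same weights apply); the fusion
network trains on canvases produced by the frozen aligner.  Stitching runs
estimate → double-H warp → fuse → outcome classification.  The outcome labels
(*error* / *failure* / *success*) operationalise a visual-inspection taxonomy
with automated geometric and photometric proxies.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry
from .alignment import (
    HomographyAligner,
    HomographyEstimate,
    estimate_homography,
)
from .fusion import SeamFusion, StitchOutput, fuse
from .synthetic import GRADES, stacked_array
from .warping import WarpedCanvas, double_h_transform

__all__ = [
    "TrainConfig",
    "OutcomeLabel",
    "EvaluationReport",
    "OutcomeThresholds",
    "train_alignment",
    "finetune_alignment",
    "train_fusion",
    "stitch",
    "classify_outcome",
    "evaluate_testset",
    "save_checkpoint",
    "load_aligner",
    "load_fusion",
]


@dataclass
class TrainConfig:
    phase1_epochs: int = 120
    phase2_epochs: int = 80
    lr: float = 1e-4
    lr_decay: float = 0.97
    batch_size: int = 8
    phase1_resolution: int = 128
    phase2_resolution: int = 512
    max_steps: int | None = None
    seed: int = 0
    checkpoint_dir: str | None = None

    def __post_init__(self):
        if self.phase1_epochs < 1 or self.phase2_epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0 or not (0 < self.lr_decay <= 1):
            raise ValueError("invalid learning-rate settings")
        for r in (self.phase1_resolution, self.phase2_resolution):
            if r % 8:
                raise ValueError("resolutions must be divisible by 8")


@dataclass
class OutcomeThresholds:
    max_condition_number: float = 1e4
    area_ratio_bounds: tuple = (0.25, 4.0)
    #: residual misalignment (mean corner px, from block-matching self-check)
    #: above which a stitch is a failure; calibrated once on synthetic
    #: validation pairs against the 5-px ground-truth rule
    max_residual_misalignment: float = 4.5
    #: minimum inlier fraction of the self-check flow; incoherent matching
    #: marks a misaligned pair even when the fitted residual is small
    min_flow_coherence: float = 0.40
    #: corner error limit (pixels) when a ground-truth homography is supplied
    max_corner_error: float = 5.0
    min_overlap: float = 1e-3


@dataclass
class OutcomeLabel:
    label: str  # success | failure | error
    diagnostics: dict = field(default_factory=dict)


@dataclass
class EvaluationReport:
    counts: dict  # grade -> {error, failure, success}
    success_rate: float  # percent
    per_pair: pd.DataFrame

    def summary(self) -> str:
        lines = ["grade     error  failure  success"]
        for g in GRADES:
            c = self.counts[g]
            lines.append(f"{g:<9} {c['error']:>5}  {c['failure']:>7}  {c['success']:>7}")
        lines.append(f"overall success rate: {self.success_rate:.2f}%")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def _config_hash(params: dict) -> str:
    return hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def save_checkpoint(estimator, path: str | Path):
    """Serialise model weights plus a hash of the architecture config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    params = estimator.get_params()
    state = estimator.model_.state_dict()
    meta = {
        "config_hash": _config_hash(params),
        "params": json.dumps(params, sort_keys=True, default=str),
        "kind": type(estimator).__name__,
    }
    np.savez(path, __meta__=json.dumps(meta), **state)


def _load(path, cls):
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        state = {k: z[k] for k in z.files if k != "__meta__"}
    if meta["kind"] != cls.__name__:
        raise ValueError(f"checkpoint holds a {meta['kind']}, expected {cls.__name__}")
    params = json.loads(meta["params"])
    est = cls()
    known = est.get_params()
    est.set_params(**{k: _coerce(v, known[k]) for k, v in params.items() if k in known})
    if meta["config_hash"] != _config_hash(est.get_params()):
        raise ValueError("incompatible checkpoint: config hash mismatch")
    return est, state


def _coerce(value, template):
    if isinstance(template, tuple) and isinstance(value, list):
        return tuple(value)
    return value


def load_aligner(path: str | Path) -> HomographyAligner:
    est, state = _load(path, HomographyAligner)
    in_ch = state["c1a.weight"].shape[1]
    est._ensure_model(in_ch)
    est.model_.load_state_dict(state)
    est.warm_start = True
    return est


def load_fusion(path: str | Path) -> SeamFusion:
    est, state = _load(path, SeamFusion)
    est._ensure_model()
    est.model_.load_state_dict(state)
    est.warm_start = True
    return est


# ---------------------------------------------------------------------------
# training wrappers
# ---------------------------------------------------------------------------

def _log_path(cfg: TrainConfig, name: str):
    if cfg.checkpoint_dir is None:
        return None
    d = Path(cfg.checkpoint_dir)
    d.mkdir(parents=True, exist_ok=True)
    return d / name


def _write_log(path, history, lr, lr_decay, steps_per_epoch):
    if path is None:
        return
    with open(path, "w") as fh:
        for step, loss in enumerate(history):
            epoch = step // max(1, steps_per_epoch)
            fh.write(
                json.dumps(
                    {"step": step, "loss": round(loss, 6), "lr": lr * lr_decay**epoch}
                )
                + "\n"
            )


def train_alignment(samples, cfg: TrainConfig, aligner: HomographyAligner | None = None):
    """Phase-1 unsupervised pre-training of the homography network."""
    if not samples:
        raise ValueError("empty dataset")
    X = stacked_array(samples)
    if X.shape[1] != cfg.phase1_resolution:
        raise ValueError(
            f"dataset resolution {X.shape[1]} != phase1_resolution {cfg.phase1_resolution}"
        )
    aligner = aligner or HomographyAligner(
        lr=cfg.lr,
        lr_decay=cfg.lr_decay,
        batch_size=cfg.batch_size,
        n_epochs=cfg.phase1_epochs,
        max_steps=cfg.max_steps,
        seed=cfg.seed,
    )
    aligner.fit(X)
    n = len(samples)
    _write_log(
        _log_path(cfg, "align_phase1.jsonl"),
        aligner.loss_history_, cfg.lr, cfg.lr_decay,
        int(np.ceil(n / aligner.batch_size)),
    )
    if cfg.checkpoint_dir:
        save_checkpoint(aligner, Path(cfg.checkpoint_dir) / "aligner.npz")
    return aligner


def finetune_alignment(samples, aligner: HomographyAligner, cfg: TrainConfig):
    """Phase-2 fine-tuning at the higher resolution, continuing from phase 1."""
    X = stacked_array(samples)
    if X.shape[1] != cfg.phase2_resolution:
        raise ValueError(
            f"dataset resolution {X.shape[1]} != phase2_resolution {cfg.phase2_resolution}"
        )
    aligner.set_params(
        warm_start=True, n_epochs=cfg.phase2_epochs, max_steps=cfg.max_steps
    )
    aligner.fit(X)
    if cfg.checkpoint_dir:
        save_checkpoint(aligner, Path(cfg.checkpoint_dir) / "aligner_finetuned.npz")
    return aligner


def train_fusion(samples, aligner: HomographyAligner, cfg: TrainConfig,
                 fusion: SeamFusion | None = None, use_true_h: bool = False):
    """Train the fusion network on canvases aligned by the (frozen) aligner."""
    if not samples:
        raise ValueError("empty dataset")
    canvases = []
    for s in samples:
        h = s.h_true if use_true_h else estimate_homography((s.reference, s.target), aligner).h
        canvases.append(double_h_transform((s.reference, s.target), h))
    fusion = fusion or SeamFusion(
        lr=cfg.lr,
        lr_decay=cfg.lr_decay,
        n_epochs=cfg.phase2_epochs,
        max_steps=cfg.max_steps,
        seed=cfg.seed,
    )
    fusion.fit(canvases)
    _write_log(
        _log_path(cfg, "fusion.jsonl"), fusion.loss_history_, cfg.lr, cfg.lr_decay,
        len(canvases),
    )
    if cfg.checkpoint_dir:
        save_checkpoint(fusion, Path(cfg.checkpoint_dir) / "fusion.npz")
    return fusion


# ---------------------------------------------------------------------------
# outcome classification
# ---------------------------------------------------------------------------

def classify_outcome(
    estimate: HomographyEstimate,
    canvas: WarpedCanvas,
    ground_truth: np.ndarray | None = None,
    thresholds: OutcomeThresholds | None = None,
) -> OutcomeLabel:
    """Label a stitch as success / failure / error with automated proxies.

    *Error*: geometrically broken output — ill-conditioned homography,
    non-convex projected quadrilateral, implausible area change, or empty
    overlap.  *Failure*: geometrically sane but misaligned — photometric
    ablation error on the overlap above threshold (or, with a ground-truth
    homography, corner error above 5 px).  Otherwise *success*.
    """
    th = thresholds or OutcomeThresholds()
    # the reference is placed by pure translation, so its footprint area is
    # exactly the frame area
    size = max(int(round(np.sqrt(canvas.mask_reference.sum()))), 8)
    diag: dict = {}
    h = estimate.h
    try:
        cond = geometry.normalized_condition_number(h, size)
    except Exception:
        cond = np.inf
    diag["condition_number"] = float(cond)
    quad = None
    try:
        quad = geometry.apply_homography(h, geometry.corner_points(size))
        diag["convex"] = geometry.quad_is_convex(quad) and (
            geometry.quad_preserves_orientation(quad)
        )
        from shapely.geometry import Polygon

        area_ratio = Polygon(quad).area / float((size - 1) ** 2)
        diag["area_ratio"] = float(area_ratio)
    except Exception:
        diag["convex"] = False
        diag["area_ratio"] = float("nan")
    overlap_px = float(canvas.overlap_mask.sum())
    diag["overlap_fraction"] = overlap_px / max(canvas.mask_reference.sum(), 1.0)
    geometric_error = (
        not np.isfinite(cond)
        or cond > th.max_condition_number
        or not diag["convex"]
        or not np.isfinite(diag["area_ratio"])
        or not (th.area_ratio_bounds[0] <= diag["area_ratio"] <= th.area_ratio_bounds[1])
        or diag["overlap_fraction"] < th.min_overlap
    )
    if geometric_error:
        return OutcomeLabel("error", diag)

    if ground_truth is not None:
        diag["corner_error"] = geometry.corner_error(h, ground_truth, size)
        ok = diag["corner_error"] <= th.max_corner_error
        return OutcomeLabel("success" if ok else "failure", diag)

    from .quality import measure_residual_misalignment

    residual, coherence = measure_residual_misalignment(canvas, size)
    diag["residual_misalignment"] = residual
    diag["flow_coherence"] = coherence
    overlap = canvas.overlap_mask
    if overlap.sum() > 0:
        diag["photometric_error"] = float(
            np.abs(canvas.warped_target - canvas.warped_reference)[overlap > 0.5].mean()
        )
    ok = (
        residual <= th.max_residual_misalignment
        and coherence >= th.min_flow_coherence
    )
    return OutcomeLabel("success" if ok else "failure", diag)


def stitch(
    pair,
    aligner: HomographyAligner,
    fusion: SeamFusion | None = None,
    ground_truth: np.ndarray | None = None,
    thresholds: OutcomeThresholds | None = None,
):
    """End-to-end stitch: estimate → double-H warp → fuse → classify.

    Any internal exception is caught and reported as an *error* outcome with
    the exception message in the diagnostics.
    """
    for name, img in zip(("reference", "target"), pair):
        if float(np.std(img)) < 1e-4:
            return (
                None,
                None,
                OutcomeLabel("error", {"reason": f"degenerate input: constant {name} image"}),
                None,
            )
    try:
        est = estimate_homography(pair, aligner)
        canvas = double_h_transform(pair, est.h)
        if fusion is not None and hasattr(fusion, "model_"):
            out = fusion.transform(canvas)
        else:
            from .fusion import average_blend

            out = StitchOutput(
                fused=average_blend(canvas),
                low_res=average_blend(canvas),
                residual=np.zeros_like(canvas.warped_reference),
            )
        label = classify_outcome(est, canvas, ground_truth, thresholds)
        return out, est, label, canvas
    except Exception as exc:  # per the outcome taxonomy: runtime errors count
        label = OutcomeLabel("error", {"exception": f"{type(exc).__name__}: {exc}"})
        return None, None, label, None


def evaluate_testset(
    samples,
    aligner: HomographyAligner,
    fusion: SeamFusion | None = None,
    use_ground_truth: bool = False,
    thresholds: OutcomeThresholds | None = None,
    csv_path: str | Path | None = None,
) -> EvaluationReport:
    """Per-grade error/failure/success counts and the overall success rate."""
    rows = []
    for i, s in enumerate(samples):
        gt = s.h_true if use_ground_truth else None
        _, est, label, _ = stitch(
            (s.reference, s.target), aligner, fusion, gt, thresholds
        )
        rows.append(
            {
                "id": i,
                "grade": s.grade,
                "overlap": s.overlap,
                "label": label.label,
                **{
                    k: v
                    for k, v in label.diagnostics.items()
                    if isinstance(v, (int, float))
                },
            }
        )
    df = pd.DataFrame(rows)
    counts = {}
    for g in GRADES:
        sub = df[df.grade == g]
        counts[g] = {
            lab: int((sub.label == lab).sum()) for lab in ("error", "failure", "success")
        }
    total = len(df)
    n_success = int((df.label == "success").sum())
    report = EvaluationReport(
        counts=counts,
        success_rate=100.0 * n_success / total if total else 0.0,
        per_pair=df,
    )
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    return report
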