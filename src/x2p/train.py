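"""Training loop, target construction, evaluation and prompt sweeps."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as M
from . import phantoms
from .config import RunConfig
from .geometry import ProjectionMatrix, projection_sampler
from .model import X2PNet, save_checkpoint
from .nn import AdamW, Tensor, stack
from .nn.tensor import no_grad
from .objectives import loss_dice_2d, loss_mse_2d, loss_3d, make_gt_heatmap

__all__ = [
    "TrainingSample",
    "load_split",
    "compute_loss",
    "train",
    "evaluate_model",
    "eval_pairs_3d",
    "sweep_prompt_displacement",
]

VIEWS = ("lat", "ap")


@dataclass
class TrainingSample:
    sample_id: str
    images: dict[str, np.ndarray]
    cameras: dict[str, ProjectionMatrix]
    prompts: dict[str, tuple[int, int]]
    landmarks_3d: np.ndarray  # (n, 3) mm, superior -> inferior
    landmarks_2d: dict[str, np.ndarray]  # view -> (n, 2)
    levels: list[str] = field(default_factory=list)
    samplers: dict | None = None  # cached unprojection plans

    @property
    def n_landmarks(self) -> int:
        return self.landmarks_3d.shape[0]


def _to_training_sample(sample: phantoms.BiplanarSample, sample_id: str) -> TrainingSample:
    return TrainingSample(
        sample_id=sample_id,
        images=sample.images,
        cameras=sample.cameras,
        prompts=sample.prompts,
        landmarks_3d=np.stack([lm.coords for lm in sample.landmarks_3d]),
        landmarks_2d=sample.landmarks_2d,
        levels=[lm.level_label for lm in sample.landmarks_3d],
    )


def load_split(dataset_dir: Path, split: str, model: X2PNet | None = None) -> list[TrainingSample]:
    """Load one split; when a model is given, precompute unprojection plans."""
    dataset_dir = Path(dataset_dir)
    manifest = phantoms.load_manifest(dataset_dir)
    samples = []
    for sample_id in manifest["splits"][split]:
        ts = _to_training_sample(phantoms.load_sample(dataset_dir / sample_id), sample_id)
        if model is not None:
            shape = ts.images["lat"].shape
            ts.samplers = {
                v: projection_sampler(ts.cameras[v], model.grid, shape) for v in VIEWS
            }
        samples.append(ts)
    return samples


def build_targets(sample: TrainingSample, config: RunConfig):
    """GT heatmaps (2, N, S, S), GT 3D coords (nv, 3) and the slot count nv.

    Slots are supervised for the leading run of landmarks visible in both
    views; remaining slots get all-zero target heatmaps.
    """
    n_slots = config.n_slots
    s = config.embed_size
    h, w = sample.images["lat"].shape
    visible = np.ones(sample.n_landmarks, dtype=bool)
    for view in VIEWS:
        uv = sample.landmarks_2d[view]
        visible &= (uv[:, 0] >= 0) & (uv[:, 0] < w) & (uv[:, 1] >= 0) & (uv[:, 1] < h)
    nv = 0
    while nv < min(sample.n_landmarks, n_slots) and visible[nv]:
        nv += 1
    gt_hm = np.zeros((2, n_slots, s, s), dtype=np.float32)
    for vi, view in enumerate(VIEWS):
        for n in range(nv):
            gt_hm[vi, n] = make_gt_heatmap(
                sample.landmarks_2d[view][n], (w, h), grid=s, sigma=config.loss_sigma
            )
    return gt_hm, sample.landmarks_3d[:nv], nv


def random_crop(sample: TrainingSample, config: RunConfig, rng: np.random.Generator):
    """Vertical crop keeping >= min_crop_vertebrae landmarks and a valid prompt.

    The same row window is applied to both views; cameras, 2D landmarks and
    prompts are re-derived.  Returns the original sample when no valid window
    is found.
    """
    h, w = sample.images["lat"].shape
    ch = config.crop_height
    if ch >= h:
        return sample
    for _ in range(8):
        off = int(rng.integers(0, h - ch + 1))
        vis = np.ones(sample.n_landmarks, dtype=bool)
        for view in VIEWS:
            uv = sample.landmarks_2d[view]
            vis &= (uv[:, 1] >= off) & (uv[:, 1] < off + ch)
        idx = np.nonzero(vis)[0]
        if idx.size < config.min_crop_vertebrae:
            continue
        run = [int(idx[0])]
        for j in idx[1:]:
            if j == run[-1] + 1:
                run.append(int(j))
            else:
                break
        run = np.array(run)
        if run.size < config.min_crop_vertebrae:
            continue
        images = {v: sample.images[v][off : off + ch, :] for v in VIEWS}
        cameras = {v: sample.cameras[v].translated(0, off) for v in VIEWS}
        lm2d = {v: sample.landmarks_2d[v][run] - np.array([0.0, off]) for v in VIEWS}
        prompts = {
            v: (int(round(lm2d[v][0, 0])), int(round(lm2d[v][0, 1]))) for v in VIEWS
        }
        ok = all(0 <= prompts[v][0] < w and 0 <= prompts[v][1] < ch for v in VIEWS)
        if not ok:
            continue
        return TrainingSample(
            sample_id=sample.sample_id + f"@crop{off}",
            images=images,
            cameras=cameras,
            prompts=prompts,
            landmarks_3d=sample.landmarks_3d[run],
            landmarks_2d=lm2d,
            levels=[sample.levels[i] for i in run],
            samplers=None,
        )
    return sample


def compute_loss(model: X2PNet, sample: TrainingSample, config: RunConfig):
    """Forward pass + LossOverall (2D heatmap MSE + Dice + normalized 3D MSE)."""
    if sample.samplers is None:
        shape = sample.images["lat"].shape
        sample.samplers = {
            v: projection_sampler(sample.cameras[v], model.grid, shape) for v in VIEWS
        }
    out = model(sample.images, sample.cameras, sample.prompts, samplers=sample.samplers)
    gt_hm, gt_coords, nv = build_targets(sample, config)
    pred_hm = stack([out["heatmaps"]["lat"], out["heatmaps"]["ap"]], axis=0)
    w1, w2, w3 = config.loss_weights
    l_mse = loss_mse_2d(pred_hm, Tensor(gt_hm))
    # Dice over supervised slots only: an all-zero target slot can never
    # reach overlap 1 with a sigmoid map (sum p^2 would have to fall below
    # eps), which otherwise leaves a large unfixable loss floor.  Empty
    # slots are still driven to zero by the MSE term.
    l_dice = loss_dice_2d(
        pred_hm[:, :nv] if 0 < nv < config.n_slots else pred_hm,
        Tensor(gt_hm[:, :nv] if 0 < nv < config.n_slots else gt_hm),
        eps=config.loss_eps,
    )
    loss = l_mse * w1 + l_dice * w2
    l_3d = 0.0
    if nv > 0:
        pred_norm = model.normalize_coords(out["result"].coords_tensor)
        gt_norm = model.normalize_coords(gt_coords).astype(np.float32)
        l_3d = loss_3d(pred_norm, Tensor(gt_norm), nv)
        loss = loss + l_3d * w3
    parts = {
        "loss": float(loss.data),
        "mse2d": float(l_mse.data),
        "dice2d": float(l_dice.data),
        "loss3d": float(l_3d.data) if nv > 0 else 0.0,
        "nv": nv,
    }
    return loss, parts, out


def eval_pairs_3d(model: X2PNet, samples, prompt_shift=None) -> list[M.EvalPair]:
    """Matched 3D prediction/GT pairs over samples (slot-index matching).

    ``prompt_shift`` optionally shifts the prompt: (view, dx, dy) applied
    before inference; samples whose shifted prompt falls outside the image
    are skipped.
    """
    pairs = []
    for sample in samples:
        prompts = dict(sample.prompts)
        if prompt_shift is not None:
            view, dx, dy = prompt_shift
            h, w = sample.images[view].shape
            x, y = prompts[view]
            x, y = x + dx, y + dy
            if not (0 <= x < w and 0 <= y < h):
                continue
            prompts[view] = (x, y)
        with no_grad():
            result = model.localize(sample.images, sample.cameras, prompts, sample.samplers)
        n_slots = result.n_slots
        for n in range(sample.n_landmarks):
            if n < n_slots:
                pairs.append(
                    M.EvalPair(
                        pred=result.coords[n],
                        gt=sample.landmarks_3d[n],
                        level=sample.levels[n] if sample.levels else f"V{n + 1}",
                        valid=bool(result.valid[n]),
                    )
                )
            else:  # more GT vertebrae than prediction slots: always a miss
                pairs.append(
                    M.EvalPair(
                        pred=np.full(3, np.nan),
                        gt=sample.landmarks_3d[n],
                        level=sample.levels[n] if sample.levels else f"V{n + 1}",
                        valid=False,
                    )
                )
    return pairs


def evaluate_model(model: X2PNet, samples, taus=(10.0, 20.0)) -> dict:
    pairs = eval_pairs_3d(model, samples)
    return M.summarize(pairs, taus=taus)


def train(
    config: RunConfig,
    max_epochs: int | None = None,
    callback=None,
) -> dict:
    """End-to-end optimization of the overall loss with AdamW.

    Gradients are accumulated over ``batch_size`` samples per step.  The best
    checkpoint (validation MPE3D) and a per-epoch CSV log are written under
    ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    epochs = max_epochs if max_epochs is not None else config.epochs
    rng = np.random.default_rng(config.seed)
    model = X2PNet(config, seed=config.seed)
    train_samples = load_split(config.dataset_dir, "train", model)
    try:
        val_samples = load_split(config.dataset_dir, "val", model)
    except KeyError:
        val_samples = []
    if not train_samples:
        raise FileNotFoundError(f"missing splits: no training samples in {config.dataset_dir}")
    opt = AdamW(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)

    history = []
    best_val = np.inf
    ckpt_path = out_dir / "checkpoint.npz"
    log_path = out_dir / "train_log.csv"
    for epoch in range(epochs):
        if config.lr_step_epoch is not None and epoch == config.lr_step_epoch:
            opt.lr *= config.lr_step_factor
        order = rng.permutation(len(train_samples))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            opt.zero_grad()
            for i in batch:
                sample = train_samples[i]
                if config.crop_augment:
                    sample = random_crop(sample, config, rng)
                loss, parts, _ = compute_loss(model, sample, config)
                if not np.isfinite(parts["loss"]):
                    raise FloatingPointError(
                        f"NaN loss at epoch {epoch}, sample {sample.sample_id}"
                    )
                (loss * (1.0 / len(batch))).backward()
                losses.append(parts["loss"])
            opt.step()
        row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_samples:
            val = evaluate_model(model, val_samples)
            row["val_mpe3d"] = val["mpe"]
            row["val_pcl3d@10"] = val["pcl@10"]
            if val["mpe"] is not None and not np.isnan(val["mpe"]) and val["mpe"] < best_val:
                best_val = val["mpe"]
                save_checkpoint(model, ckpt_path, extra={"epoch": epoch, "val_mpe3d": best_val})
        history.append(row)
        if callback is not None and callback(epoch, row, model):
            break  # callback requested an early stop
    if not val_samples or not np.isfinite(best_val):
        save_checkpoint(model, ckpt_path, extra={"epoch": epochs - 1})
    with open(log_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=sorted({k for r in history for k in r}))
        writer.writeheader()
        writer.writerows(history)
    return {"model": model, "history": history, "checkpoint": ckpt_path, "log": log_path}


def sweep_prompt_displacement(
    model: X2PNet,
    samples,
    axis: str = "x",
    offsets=(-20, -10, 0, 10, 20),
    view: str = "lat",
    taus=(10.0, 20.0),
) -> pd.DataFrame:
    """Evaluate with the prompt shifted along one axis of one view.

    Offset 0 reproduces the unperturbed evaluation exactly.  Samples whose
    shifted prompt leaves the image are skipped and counted.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    rows = []
    for off in offsets:
        shift = (view, off, 0) if axis == "x" else (view, 0, off)
        pairs = eval_pairs_3d(model, samples, prompt_shift=shift if off != 0 else None)
        n_total = sum(s.n_landmarks for s in samples)
        summary = M.summarize(pairs, taus=taus) if pairs else {}
        rows.append(
            {
                "view": view,
                "axis": axis,
                "offset": off,
                **{k: v for k, v in summary.items()},
                "n_skipped_landmarks": n_total - len(pairs),
            }
        )
    return pd.DataFrame(rows)
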