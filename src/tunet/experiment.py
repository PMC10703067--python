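"""Training, evaluation, ablation and statistical comparison harness.

Training follows the reference optimization recipe: mini-batch SGD with
momentum 0.9 and weight decay 1e-4, initial learning rate 0.01 stepped down
every ``lr_step_epochs`` epochs, batch size 10, under the Dice + TopK joint
loss.  All randomness (shuffling, initialization) fans out from one root
seed, so a fixed seed reproduces the run bit-for-bit on one device.

Model comparison uses the nonparametric Friedman test on per-image metric
values: algorithms are ranked within each image (average ranks on ties,
rank M = best, so a *higher* mean rank means better performance) and the
tie-corrected chi-square statistic is referred to a chi-square distribution
with M - 1 degrees of freedom.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import nn
from .autodiff import Tensor
from .losses import LossConfig, joint_loss
from .metrics import aggregate_records, evaluate_pair, records_to_frame
from .network import ModelConfig, build_model
from .synthetic import Sample

__all__ = [
    "TrainConfig", "TrainResult", "FriedmanResult", "train", "evaluate_model",
    "run_ablation", "friedman_test", "summarize_report",
    "save_checkpoint", "load_checkpoint",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the reference recipe)."""

    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 10
    epochs: int = 1
    lr_step_epochs: int = 100
    lr_decay_factor: float = 0.1
    max_iters: int | None = None       # optional hard cap on update steps
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    model: ModelConfig = field(default_factory=ModelConfig)

    def validate(self) -> None:
        if self.lr <= 0 or self.lr_decay_factor <= 0:
            raise ValueError("learning rates must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.lr_step_epochs < 1:
            raise ValueError("lr_step_epochs must be >= 1")
        self.loss.validate()
        self.model.validate()


@dataclass
class TrainResult:
    model: object
    history: pd.DataFrame   # per-iteration loss breakdown (+ per-epoch val dice)
    config: TrainConfig


def _stack(samples) -> tuple:
    x = np.stack([s.image for s in samples]).astype(nn.DTYPE)[:, None]
    y = np.stack([s.mask for s in samples]).astype(np.uint8)[:, None]
    return x, y


def train(train_set, val_set=None, cfg: TrainConfig | None = None,
          model=None) -> TrainResult:
    """Train a model on a list of :class:`Sample`.

    A fresh model is built from ``cfg.model`` unless one is passed in
    (``epochs=0`` therefore returns the untouched initialization).  Raises
    ``FloatingPointError`` if the loss diverges to a non-finite value.
    """
    cfg = cfg or TrainConfig()
    cfg.validate()
    if not train_set:
        raise ValueError("train_set must be nonempty")
    if model is None:
        model = build_model(cfg.model, seed=cfg.seed)
    opt = nn.SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum,
                 weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    rows = []
    it = 0
    stop = False
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr * cfg.lr_decay_factor ** (epoch // cfg.lr_step_epochs)
        order = rng.permutation(len(train_set))
        model.train()
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_set[i] for i in order[start:start + cfg.batch_size]]
            x, y = _stack(batch)
            probs = model(Tensor(x, requires_grad=False))
            res = joint_loss(probs, y, cfg.loss)
            total = res.total.item()
            if not np.isfinite(total):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} iter {it}: loss={total}")
            opt.zero_grad()
            res.total.backward()
            opt.step()
            row = {"epoch": epoch, "iter": it, "lr": opt.lr, "loss": total}
            row.update({f"loss_{c}": v for c, v in res.breakdown().items()})
            rows.append(row)
            it += 1
            if cfg.max_iters is not None and it >= cfg.max_iters:
                stop = True
                break
        if val_set:
            _, summary = evaluate_model(model, val_set)
            vd = float(summary.loc[summary.metric == "dice", "mean"].iloc[0])
            if rows:
                rows[-1]["val_dice"] = vd
        if stop:
            break
    history = pd.DataFrame(rows)
    return TrainResult(model=model, history=history, config=cfg)


def predict_proba(model, samples, batch_size: int = 10) -> np.ndarray:
    """Eval-mode probability maps for a list of samples, shape (n, H, W)."""
    model.eval()
    outs = []
    for start in range(0, len(samples), batch_size):
        x, _ = _stack(samples[start:start + batch_size])
        outs.append(model(Tensor(x)).data[:, 0])
    return np.concatenate(outs, axis=0)


def evaluate_model(model, test_set, spacing: float | None = None,
                   threshold: float = 0.5) -> tuple:
    """Per-image metric table plus mean ± std summary.

    ``spacing=None`` uses each sample's own mm/px value; distances of
    degenerate (empty-mask) pairs are excluded from the summary, with the
    exclusion count reported.
    """
    probs = predict_proba(model, test_set)
    records = []
    for p, s in zip(probs, test_set):
        sp = s.spacing if spacing is None else spacing
        records.append(evaluate_pair(p, s.mask, spacing=sp, threshold=threshold,
                                     image_id=s.id))
    return records_to_frame(records), aggregate_records(records)


def run_ablation(grid, train_set, test_set, cfg: TrainConfig | None = None):
    """Train/evaluate each (name, ModelConfig, LossConfig) arm on shared data.

    Every arm uses the same seed and data ordering; returns the per-image
    Dice matrix (images x arms), ready for :func:`friedman_test`, plus
    boxplot-ready summaries (median, quartiles, whiskers) and parameter
    counts per arm.
    """
    cfg = cfg or TrainConfig()
    columns = {}
    summaries = []
    for name, model_cfg, loss_cfg in grid:
        arm_cfg = TrainConfig(**{**asdict_shallow(cfg),
                                 "model": model_cfg, "loss": loss_cfg})
        result = train(list(train_set), None, arm_cfg)
        table, _ = evaluate_model(result.model, list(test_set))
        dice = table["dice"].to_numpy(dtype=float)
        columns[name] = dice
        q1, med, q3 = np.percentile(dice, [25, 50, 75])
        summaries.append({
            "arm": name, "median": med, "q1": q1, "q3": q3,
            "whisker_lo": dice.min(), "whisker_hi": dice.max(),
            "mean": dice.mean(), "n_parameters": result.model.num_parameters(),
        })
    index = [s.id for s in test_set]
    return pd.DataFrame(columns, index=index), pd.DataFrame(summaries)


def asdict_shallow(cfg: TrainConfig) -> dict:
    d = dict(cfg.__dict__)
    return d


@dataclass
class FriedmanResult:
    chi_square: float
    p_value: float
    mean_ranks: pd.Series   # one per algorithm; higher = better
    n_images: int
    n_algorithms: int


def friedman_test(table, higher_is_better: bool = True) -> FriedmanResult:
    """Friedman test over an images x algorithms metric table.

    Within each image the M algorithms are ranked 1..M with average ranks on
    ties; rank M goes to the best value (for ``higher_is_better``), so higher
    mean ranks indicate better performance.  The chi-square statistic uses
    the standard tie correction and M - 1 degrees of freedom.
    """
    df = pd.DataFrame(table)
    vals = df.to_numpy(dtype=float)
    n, m = vals.shape
    if m < 2 or n < 2:
        raise ValueError(f"need >= 2 algorithms and >= 2 images, got {m} x {n}")
    if np.isnan(vals).any():
        raise ValueError("metric table contains missing cells")
    data = vals if higher_is_better else -vals
    ranks = np.apply_along_axis(stats.rankdata, 1, data)  # rank m = best
    mean_ranks = ranks.mean(axis=0)
    chi = 12.0 * n / (m * (m + 1)) * np.sum((mean_ranks - (m + 1) / 2.0) ** 2)
    # tie correction: divide by 1 - sum(t^3 - t) / (n m (m^2 - 1))
    ties = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts ** 3 - counts)
    denom = 1.0 - ties / (n * m * (m ** 2 - 1))
    if denom <= 0:  # all algorithms identical on every image
        chi_corr = 0.0
        p = 1.0
    else:
        chi_corr = chi / denom
        p = float(stats.chi2.sf(chi_corr, m - 1))
    return FriedmanResult(
        chi_square=float(chi_corr), p_value=p,
        mean_ranks=pd.Series(mean_ranks, index=df.columns),
        n_images=n, n_algorithms=m)


def summarize_report(metric_tables: dict, out_dir: str,
                     friedman: FriedmanResult | None = None,
                     parameter_counts: dict | None = None) -> str:
    """Render a deterministic CSV + Markdown report.

    ``metric_tables`` maps arm name -> per-image metric DataFrame (as from
    :func:`evaluate_model`).  Returns the Markdown text; files are written
    under ``out_dir`` (summary.csv, report.md).
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for name in sorted(metric_tables):
        table = metric_tables[name]
        for metric in ("dice", "precision", "recall", "hd", "asd"):
            vals = table[metric].to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            rows.append({"arm": name, "metric": metric,
                         "mean": vals[ok].mean() if ok.any() else np.nan,
                         "std": vals[ok].std() if ok.any() else np.nan,
                         "n": int(ok.sum())})
    summary = pd.DataFrame(rows)
    summary.to_csv(os.path.join(out_dir, "summary.csv"), index=False)
    lines = ["# Segmentation report", "", "## Metric summary (mean ± std)", ""]
    if not summary.empty:
        lines.append("| arm | dice | precision | recall | hd (mm) | asd (mm) |")
        lines.append("|---|---|---|---|---|---|")
        for name in sorted(metric_tables):
            sub = summary[summary.arm == name].set_index("metric")
            cells = [f"{sub.loc[mt, 'mean']:.4f} ± {sub.loc[mt, 'std']:.4f}"
                     if np.isfinite(sub.loc[mt, "mean"]) else "n/a"
                     for mt in ("dice", "precision", "recall", "hd", "asd")]
            lines.append("| " + " | ".join([name] + cells) + " |")
    if friedman is not None:
        lines += ["", "## Friedman test", "",
                  f"chi-square = {friedman.chi_square:.4f}, "
                  f"p = {friedman.p_value:.3g} "
                  f"({friedman.n_algorithms} algorithms, "
                  f"{friedman.n_images} images)", "",
                  "| arm | mean rank |", "|---|---|"]
        for name, r in friedman.mean_ranks.items():
            lines.append(f"| {name} | {r:.3f} |")
    if parameter_counts:
        lines += ["", "## Trainable parameters", "", "| arm | parameters |",
                  "|---|---|"]
        for name in sorted(parameter_counts):
            lines.append(f"| {name} | {parameter_counts[name]} |")
    text = "\n".join(lines) + "\n"
    with open(os.path.join(out_dir, "report.md"), "w") as fh:
        fh.write(text)
    return text


def save_checkpoint(model, cfg: TrainConfig, path: str) -> None:
    """Write weights (npz) plus a JSON sidecar with the full configuration."""
    np.savez(path, **model.state_dict())
    side = {
        "model": dict(asdict(cfg.model)),
        "loss": dict(asdict(cfg.loss)),
        "train": {k: v for k, v in cfg.__dict__.items()
                  if k not in ("model", "loss")},
    }
    with open(path + ".json", "w") as fh:
        json.dump(side, fh, indent=2, default=lambda o: list(o)
                  if isinstance(o, tuple) else o)


def load_checkpoint(path: str):
    """Rebuild the model from a checkpoint written by :func:`save_checkpoint`."""
    with open(path + ".json") as fh:
        side = json.load(fh)
    mc = side["model"]
    for key in ("base_channels", "atrous_rates", "pool_fields"):
        mc[key] = tuple(mc[key])
    model_cfg = ModelConfig(**mc)
    model = build_model(model_cfg, seed=side["train"].get("seed", 0))
    npz_path = path if path.endswith(".npz") else path + ".npz"
    if not os.path.exists(npz_path):
        npz_path = path
    with np.load(npz_path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model, model_cfg
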