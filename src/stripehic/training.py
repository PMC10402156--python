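"""Two-stage optimization with augmentation, masking, early stopping and
one-epoch fine-tuning for deconvolution."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .coaccess import subsample_for_augmentation
from .dataset import StripeDataset, WindowExample
from .model import VStripeModel


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-6
    weight_decay: float = 1e-3
    momentum: float = 0.9
    max_epochs: int = 30
    patience: int = 10
    batch_size: int = 8
    cell_subsample: tuple[int, int] = (500, 5000)
    metacell_subsample: tuple[int, int] = (400, 1000)
    shift_choices: tuple[int, ...] = (-50, 50)
    start_buffer_bp: int = 4_000_000
    end_buffer_bp: int = 5_000_000
    val_chroms: tuple[str, ...] = ("chr3", "chr15")
    test_chroms: tuple[str, ...] = ("chr5", "chr18", "chr20", "chr21")
    centers_per_epoch: int = 512
    val_centers: int = 128
    max_grad_norm: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")

    @classmethod
    def mini(cls, **overrides) -> "TrainConfig":
        """Desk-scale preset: miniature geometry needs a larger lr and small
        buffers/subsample ranges."""
        base = cls(lr=1e-3, max_epochs=12, patience=5,
                   cell_subsample=(200, 500), metacell_subsample=(40, 120),
                   start_buffer_bp=250_000, end_buffer_bp=250_000,
                   val_chroms=("chr2",), test_chroms=("chr3",),
                   centers_per_epoch=48, val_centers=24, max_grad_norm=10.0)
        return replace(base, **overrides)


def train_chroms(dataset: StripeDataset, config: TrainConfig) -> list[str]:
    held = set(config.val_chroms) | set(config.test_chroms)
    return [c for c in dataset.layout.chrom_names if c not in held]


def valid_centers(dataset: StripeDataset, chrom: str,
                  config: TrainConfig) -> np.ndarray:
    """Center bins whose position respects the start/end buffers."""
    g = dataset.geometry
    length = dataset.layout.length(chrom)
    n_bins = dataset.layout.bin_count(chrom, g.hic_resolution)
    t_min = -(-config.start_buffer_bp // g.hic_resolution)
    t_max = (length - config.end_buffer_bp) // g.hic_resolution
    t_max = min(t_max, n_bins - 1)
    if t_max < t_min:
        return np.array([], dtype=int)
    return np.arange(t_min, t_max + 1)


def make_training_example(dataset: StripeDataset, chrom: str, t: int,
                          rng: np.random.Generator,
                          config: TrainConfig) -> WindowExample:
    """One augmented example: fresh cell and metacell subsamples plus a
    random ±50bp shift of all input tracks."""
    centers = valid_centers(dataset, chrom, config)
    if centers.size == 0 or not centers[0] <= t <= centers[-1]:
        raise ValueError(f"center {t} outside buffered region of {chrom}")
    cell_idx = subsample_for_augmentation(dataset.n_cells,
                                          config.cell_subsample, rng)
    n_meta = dataset.metacells.n_metacells
    meta_idx = subsample_for_augmentation(n_meta, config.metacell_subsample,
                                          rng)
    shift = int(rng.choice(config.shift_choices))
    return dataset.example(chrom, t, cell_idx=cell_idx, metacell_idx=meta_idx,
                           shift_bp=shift)


def masked_mse(pred: nn.Tensor, target: np.ndarray,
               valid: np.ndarray) -> nn.Tensor:
    """MSE over valid entries only; an all-invalid target contributes 0."""
    m = valid.astype(float)
    denom = max(m.sum(), 1.0)
    diff = pred - nn.Tensor(target * m)
    return (diff * diff * nn.Tensor(m)).sum() * (1.0 / denom)


def masked_mse_value(pred: np.ndarray, target: np.ndarray,
                     valid: np.ndarray) -> float:
    if valid.sum() == 0:
        return 0.0
    d = (pred - target)[valid]
    return float(np.mean(d * d))


def _batch_loss(model: VStripeModel, examples: list[WindowExample],
                stage: int) -> nn.Tensor:
    """Mean masked MSE over both stripe sides of a batch."""
    acc = np.stack([e.acc_ctcf for e in examples])
    coacc = np.stack([e.coacc for e in examples])
    tgt_r = np.stack([e.target_right.values for e in examples])
    val_r = np.stack([e.target_right.valid for e in examples])
    tgt_l = np.stack([e.target_left.values for e in examples])
    val_l = np.stack([e.target_left.valid for e in examples])
    pred_r = model.forward_one_side(nn.Tensor(acc), nn.Tensor(coacc),
                                    stage=stage)
    r_acc, r_co = VStripeModel.reverse_inputs(acc, coacc)
    pred_l = model.forward_one_side(nn.Tensor(r_acc), nn.Tensor(r_co),
                                    stage=stage)
    loss_r = masked_mse(pred_r, tgt_r, val_r)
    loss_l = masked_mse(pred_l, tgt_l, val_l)
    return (loss_r + loss_l) * 0.5


def _epoch_centers(dataset: StripeDataset, chroms: list[str],
                   config: TrainConfig,
                   rng: np.random.Generator) -> list[tuple[str, int]]:
    pool: list[tuple[str, int]] = []
    for chrom in chroms:
        pool.extend((chrom, int(t)) for t in valid_centers(dataset, chrom,
                                                           config))
    if not pool:
        raise ValueError("no valid training centers inside the buffers")
    rng.shuffle(pool)
    return pool[:config.centers_per_epoch]


def _validation_set(dataset: StripeDataset, config: TrainConfig
                    ) -> list[WindowExample]:
    """Fixed, unaugmented validation examples (full population, no shift)."""
    out: list[WindowExample] = []
    chroms = [c for c in config.val_chroms if c in dataset.layout.lengths]
    for chrom in chroms:
        centers = valid_centers(dataset, chrom, config)
        if centers.size == 0:
            continue
        take = centers[np.linspace(0, centers.size - 1,
                                   min(config.val_centers, centers.size),
                                   dtype=int)]
        for t in np.unique(take):
            out.append(dataset.example(chrom, int(t)))
    return out


def _evaluate(model: VStripeModel, examples: list[WindowExample],
              stage: int) -> float:
    model.eval()
    losses = []
    bs = 16
    for i in range(0, len(examples), bs):
        batch = examples[i:i + bs]
        acc = np.stack([e.acc_ctcf for e in batch])
        coacc = np.stack([e.coacc for e in batch])
        pred_r = model.predict_one_side(acc, coacc, stage=stage)
        r_acc, r_co = VStripeModel.reverse_inputs(acc, coacc)
        pred_l = model.predict_one_side(r_acc, r_co, stage=stage)
        for k, e in enumerate(batch):
            losses.append(masked_mse_value(pred_r[k], e.target_right.values,
                                           e.target_right.valid))
            losses.append(masked_mse_value(pred_l[k], e.target_left.values,
                                           e.target_left.valid))
    return float(np.mean(losses)) if losses else 0.0


def _fit(model: VStripeModel, dataset: StripeDataset, config: TrainConfig,
         stage: int, params: list[nn.Tensor],
         freeze_fe1_stats: bool = False,
         max_epochs: int | None = None,
         early_stop: bool = True) -> list[dict]:
    rng = np.random.default_rng(config.seed + stage)
    opt = nn.SGD(params, lr=config.lr, momentum=config.momentum,
                 weight_decay=config.weight_decay,
                 max_grad_norm=config.max_grad_norm)
    chroms = train_chroms(dataset, config)
    val_examples = _validation_set(dataset, config)
    history: list[dict] = []
    best_loss = np.inf
    best_state = None
    since_best = 0
    n_epochs = config.max_epochs if max_epochs is None else max_epochs
    for epoch in range(n_epochs):
        model.train()
        if freeze_fe1_stats:
            model.fe1.eval()  # keep FE1 batch-norm buffers bit-identical
        centers = _epoch_centers(dataset, chroms, config, rng)
        epoch_losses = []
        for i in range(0, len(centers), config.batch_size):
            batch = [make_training_example(dataset, c, t, rng, config)
                     for c, t in centers[i:i + config.batch_size]]
            loss = _batch_loss(model, batch, stage)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        val_loss = _evaluate(model, val_examples, stage) if val_examples \
            else float(np.mean(epoch_losses))
        history.append({"epoch": epoch,
                        "train_loss": float(np.mean(epoch_losses)),
                        "val_loss": val_loss})
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.get_state()
            since_best = 0
        else:
            since_best += 1
            if early_stop and since_best >= config.patience:
                break
    if early_stop and best_state is not None:
        model.set_state(best_state)
    model.eval()
    return history


def train_stage1(model: VStripeModel, dataset: StripeDataset,
                 config: TrainConfig) -> list[dict]:
    """Optimize FE1 plus the dummy linear head against the masked targets."""
    return _fit(model, dataset, config, stage=1,
                params=model.stage1_parameters())


def train_stage2(model: VStripeModel, dataset: StripeDataset,
                 config: TrainConfig) -> list[dict]:
    """Freeze FE1 and optimize FE2 plus the final linear predictor.

    The final head is warm-started from the stage-1 dummy head (FE2 columns
    zeroed) so stage 2 begins exactly at the stage-1 solution and learns the
    co-accessibility contribution additively.
    """
    d1 = model.config.d1
    model.head.w.data[:d1, :] = model.dummy_head.w.data
    model.head.w.data[d1:, :] = 0.0
    model.head.b.data[...] = model.dummy_head.b.data
    return _fit(model, dataset, config, stage=2,
                params=model.stage2_parameters(), freeze_fe1_stats=True)


def finetune(model: VStripeModel, dataset: StripeDataset, config: TrainConfig,
             epochs: int = 1) -> list[dict]:
    """Fine-tune all parameters for a fixed number of epochs (default 1) on
    the training chromosomes only — the deconvolution adaptation step."""
    return _fit(model, dataset, config, stage=2, params=model.parameters(),
                max_epochs=epochs, early_stop=False)
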