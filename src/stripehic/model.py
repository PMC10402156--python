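"""Two-feature-extractor network mapping one window's inputs to a one-sided
V-stripe prediction.

Feature extractor 1 consumes the 2 x L0 accessibility+CTCF tracks through 15
conv1d/BN/ReLU blocks (pooled down to one position per contact-map bin),
joins pairs of positions by outer-concatenation with an average-pooled input
skip connection, applies three conv2d layers, and reads out the center row.
Feature extractor 2 consumes the 20 x coacc_window_len Jaccard slice. The
final linear layer predicts the right side of the V-stripe; the left side is
predicted from the mirrored input with shared weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .geometry import ModelGeometry


@dataclass(frozen=True)
class ModelConfig:
    """Layer hyperparameters (the published text fixes only block counts and
    total pooling; kernels/channels/pool placement are configurable)."""

    channels1: tuple[int, ...] = (16,) * 5 + (32,) * 5 + (64,) * 5
    kernel1: int = 5
    # pool factors applied after these (1-based) conv blocks; product must
    # equal geometry.reduction_factor
    pool_after: tuple[int, ...] = (3, 6, 9, 12, 15)
    pool_factors: tuple[int, ...] = (2, 2, 2, 5, 5)
    conv2d_channels: tuple[int, ...] = (32, 32, 32)
    kernel2d: int = 3
    d1: int = 32
    fe2_channels: int = 32
    kernel2: int = 5
    d2: int = 32

    @classmethod
    def small(cls) -> "ModelConfig":
        """Light preset for the miniature test geometry: pool early so the
        deep blocks run at short lengths."""
        return cls(channels1=(8,) * 15,
                   pool_after=(1, 2, 3, 4, 5),
                   pool_factors=(2, 2, 2, 5, 5),
                   conv2d_channels=(12, 12, 12),
                   d1=12, fe2_channels=12, d2=12)


class FeatureExtractor1(nn.Module):
    """Accessibility + CTCF -> per-contact-bin features (N, L, d1)."""

    def __init__(self, geometry: ModelGeometry, config: ModelConfig,
                 rng: np.random.Generator):
        super().__init__()
        if int(np.prod(config.pool_factors)) != geometry.reduction_factor:
            raise ValueError("pool factors must multiply to the reduction factor")
        if len(config.channels1) != 15:
            raise ValueError("feature extractor 1 uses 15 conv blocks")
        self.geometry = geometry
        self.config = config
        self.convs: list[nn.Conv1d] = []
        self.bns: list[nn.BatchNorm1d] = []
        cin = 2
        for c in config.channels1:
            self.convs.append(nn.Conv1d(cin, c, config.kernel1, rng))
            self.bns.append(nn.BatchNorm1d(c))
            cin = c
        self._pool = dict(zip(config.pool_after, config.pool_factors))
        c1 = config.channels1[-1]
        self.convs2d: list[nn.Conv2d] = []
        cin2 = 2 * c1 + 4  # pairwise features + 2-channel input skip
        for c in config.conv2d_channels:
            self.convs2d.append(nn.Conv2d(cin2, c, config.kernel2d, rng))
            cin2 = c
        self.readout = nn.Linear(config.conv2d_channels[-1], config.d1, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        geom = self.geometry
        h = x
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns), start=1):
            h = bn(conv(h)).relu()
            if i in self._pool:
                h = nn.avg_pool1d(h, self._pool[i])
        # h: (N, C1, L) -> pairwise (N, L, L, 2C1)
        per_pos = h.transpose(0, 2, 1)
        pair = nn.outer_concat(per_pos)
        skip = nn.avg_pool1d(x, geom.reduction_factor).transpose(0, 2, 1)
        pair = nn.concat([pair, nn.outer_concat(skip)], axis=-1)
        h2 = pair.transpose(0, 3, 1, 2)
        for conv in self.convs2d:
            h2 = conv(h2).relu()
        t_idx = geom.center_offset_bins
        row = h2[:, :, t_idx, :].transpose(0, 2, 1)  # (N, L, C)
        return self.readout(row)

    def pairwise_latent(self, x: nn.Tensor) -> nn.Tensor:
        """Pairwise tensor before the conv2d stack (probe for tests)."""
        h = x
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns), start=1):
            h = bn(conv(h)).relu()
            if i in self._pool:
                h = nn.avg_pool1d(h, self._pool[i])
        return nn.outer_concat(h.transpose(0, 2, 1))


class ResidualBlock1d(nn.Module):
    def __init__(self, c: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv1d(c, c, k, rng)
        self.bn1 = nn.BatchNorm1d(c)
        self.conv2 = nn.Conv1d(c, c, k, rng)
        self.bn2 = nn.BatchNorm1d(c)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        return (h + x).relu()


class FeatureExtractor2(nn.Module):
    """Jaccard co-accessibility slice -> per-distance features (N, out_len, d2).

    The 20 center bins act as input channels; convolution runs along the
    genomic axis, which is then pooled to one position per contact-map bin
    and restricted to the right half of the window.
    """

    def __init__(self, geometry: ModelGeometry, config: ModelConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.geometry = geometry
        c = config.fe2_channels
        k = config.kernel2
        cin = geometry.center_coacc_bins
        self.pre = [nn.Conv1d(cin, c, k, rng), nn.Conv1d(c, c, k, rng),
                    nn.Conv1d(c, c, k, rng)]
        self.pre_bns = [nn.BatchNorm1d(c) for _ in range(3)]
        self.res = [ResidualBlock1d(c, k, rng), ResidualBlock1d(c, k, rng)]
        self.post = [nn.Conv1d(c, c, k, rng), nn.Conv1d(c, c, k, rng),
                     nn.Conv1d(c, c, k, rng)]
        self.post_bns = [nn.BatchNorm1d(c) for _ in range(3)]
        self.readout = nn.Linear(c, config.d2, rng)

    def __call__(self, coacc: nn.Tensor) -> nn.Tensor:
        geom = self.geometry
        h = coacc
        for conv, bn in zip(self.pre, self.pre_bns):
            h = bn(conv(h)).relu()
        for block in self.res:
            h = block(h)
        for conv, bn in zip(self.post, self.post_bns):
            h = bn(conv(h)).relu()
        # pool coacc bins down to contact-map bins, keep center..right edge
        factor = geom.coacc_window_len // geom.hic_window_bins
        h = nn.avg_pool1d(h, factor)
        start = geom.center_offset_bins
        h = h[:, :, start:start + geom.out_len]
        return self.readout(h.transpose(0, 2, 1))


class VStripeModel(nn.Module):
    """Full model: FE1 + FE2 + linear predictor, plus the stage-1 dummy head."""

    def __init__(self, geometry: ModelGeometry,
                 config: ModelConfig | None = None, seed: int = 0):
        super().__init__()
        config = config or ModelConfig()
        rng = np.random.default_rng(seed)
        self.geometry = geometry
        self.config = config
        self.fe1 = FeatureExtractor1(geometry, config, rng)
        self.fe2 = FeatureExtractor2(geometry, config, rng)
        self.head = nn.Linear(config.d1 + config.d2, 1, rng)
        self.dummy_head = nn.Linear(config.d1, 1, rng)

    # -- forward ----------------------------------------------------------
    def forward_one_side(self, acc_ctcf: nn.Tensor, coacc: nn.Tensor,
                         stage: int = 2) -> nn.Tensor:
        """Predict the right-side stripe: (N, out_len)."""
        geom = self.geometry
        f1 = self.fe1(acc_ctcf)
        f1r = f1[:, geom.center_offset_bins:geom.center_offset_bins
                 + geom.out_len, :]
        if stage == 1:
            out = self.dummy_head(f1r)
        else:
            f2 = self.fe2(coacc)
            out = self.head(nn.concat([f1r, f2], axis=-1))
        return out.reshape(out.shape[0], geom.out_len)

    @staticmethod
    def reverse_inputs(acc_ctcf: np.ndarray,
                       coacc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Mirror a window: flip tracks along the genomic axis and reorder
        the co-accessibility center-bin channels."""
        return (acc_ctcf[..., ::-1].copy(),
                coacc[..., ::-1, ::-1].copy() if coacc.ndim == 2
                else coacc[:, ::-1, ::-1].copy())

    def predict_one_side(self, acc_ctcf: np.ndarray, coacc: np.ndarray,
                         stage: int = 2) -> np.ndarray:
        """Inference-mode right-side prediction for a batch or one example."""
        single = acc_ctcf.ndim == 2
        if single:
            acc_ctcf = acc_ctcf[None]
            coacc = coacc[None]
        was_training = self.training
        self.eval()
        out = self.forward_one_side(nn.Tensor(acc_ctcf), nn.Tensor(coacc),
                                    stage=stage).data
        if was_training:
            self.train()
        return out[0] if single else out

    def predict_vstripe(self, acc_ctcf: np.ndarray, coacc: np.ndarray,
                        stage: int = 2) -> tuple[np.ndarray, np.ndarray]:
        """(left, right) stripes; left is the right-side prediction of the
        mirrored input (shared weights)."""
        right = self.predict_one_side(acc_ctcf, coacc, stage=stage)
        r_acc, r_co = self.reverse_inputs(acc_ctcf, coacc)
        left = self.predict_one_side(r_acc, r_co, stage=stage)
        return left, right

    # -- parameter groups ---------------------------------------------------
    def stage1_parameters(self) -> list[nn.Tensor]:
        return self.fe1.parameters() + self.dummy_head.parameters()

    def stage2_parameters(self) -> list[nn.Tensor]:
        return self.fe2.parameters() + self.head.parameters()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def outer_concat_array(f: np.ndarray) -> np.ndarray:
    """Plain-numpy outer-concatenation: (L, C) -> (L, L, 2C)."""
    return nn.outer_concat(nn.Tensor(f[None])).data[0]


CHECKPOINT_VERSION = 1


def save_model(model: VStripeModel, path) -> None:
    """Self-describing checkpoint: geometry + layer config + all arrays."""
    import json

    meta = {
        "version": CHECKPOINT_VERSION,
        "geometry": {f: getattr(model.geometry, f)
                     for f in ("hic_resolution", "acc_resolution",
                               "coacc_resolution", "window_bp",
                               "max_distance_bp")},
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(model.config).items()},
    }
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path) -> VStripeModel:
    import json

    with np.load(path, allow_pickle=False) as f:
        meta = json.loads(str(f["meta"]))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        geometry = ModelGeometry(**meta["geometry"])
        cfg = {k: (tuple(v) if isinstance(v, list) else v)
               for k, v in meta["config"].items()}
        model = VStripeModel(geometry, ModelConfig(**cfg))
        n = len(model.state_arrays())
        model.set_state([f[f"arr_{i}"] for i in range(n)])
    model.eval()
    return model
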