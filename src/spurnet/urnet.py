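"""UrNet: a UNet-shaped encoder-decoder with a ResNet18-style residual encoder.

The encoder is a 7×7 stride-2 stem followed by four stages of basic residual
units (two 3×3 conv+BN+ReLU with an identity shortcut; the first unit of
stages 2-4 downsamples by stride 2), giving skip features at 1/2, 1/4, 1/8
and a 1/16 bottleneck. The decoder mirrors the encoder: each level doubles
the resolution bilinearly, concatenates the same-resolution encoder feature
map and applies two 3×3 conv+BN+ReLU; a final upsample returns to full
resolution and a 1×1 convolution produces the two per-pixel class scores
(background / tongue). Dropout is applied at the bottleneck only.

Training uses Adam on pixelwise cross-entropy with an inverse-time learning
rate decay lr(t) = lr0 / (1 + decay·t), where t counts optimizer steps, and
early stopping once the monitored loss has not improved for ``patience``
consecutive epochs; the best-loss weights are restored on exit.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, asdict, field

import numpy as np

from . import nn
from .io_formats import NORMALIZED, RgbImage, SegMask


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes NaN or infinite."""


@dataclass
class UrNetConfig:
    input_side: int = 256
    in_channels: int = 3
    num_classes: int = 2
    encoder_channels: tuple = (64, 128, 256, 512)
    blocks_per_stage: int = 2
    dropout_rate: float = 0.6
    width_multiplier: float = 1.0

    def __post_init__(self):
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.input_side % self.total_downsampling != 0:
            raise ValueError(
                f"input_side {self.input_side} not divisible by the total "
                f"downsampling factor {self.total_downsampling}"
            )

    @property
    def total_downsampling(self) -> int:
        return 16  # stem /2, then three stride-2 stage transitions

    @property
    def widths(self) -> list[int]:
        return [max(2, int(round(c * self.width_multiplier))) for c in self.encoder_channels]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["encoder_channels"] = list(self.encoder_channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "UrNetConfig":
        d = dict(d)
        d["encoder_channels"] = tuple(d.get("encoder_channels", (64, 128, 256, 512)))
        return cls(**d)


@dataclass
class TrainConfig:
    lr0: float = 1e-3
    decay: float = 1e-4
    optimizer: str = "adam"
    loss: str = "cross-entropy"
    patience: int = 10
    max_epochs: int = 100
    batch_size: int = 4
    seed: int = 0
    monitor: str = "train"  # or "val"

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.decay < 0:
            raise ValueError("decay must be >= 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.monitor not in ("train", "val"):
            raise ValueError("monitor must be 'train' or 'val'")


@dataclass
class TrainHistory:
    epochs: list = field(default_factory=list)  # dicts: epoch, loss, val_loss, lr
    stop_epoch: int = 0
    stop_reason: str = "max_epochs"

    def losses(self) -> list[float]:
        return [e["loss"] for e in self.epochs]

    def to_csv(self, path) -> None:
        cols = ["epoch", "loss", "val_loss", "lr"]
        lines = [",".join(cols)]
        for e in self.epochs:
            lines.append(",".join(str(e.get(c, "")) for c in cols))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def lr_schedule(lr0: float, decay: float, iteration: int) -> float:
    """Inverse-time decay: lr0 / (1 + decay · iteration)."""
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    return lr0 / (1.0 + decay * iteration)


class EarlyStopping:
    """Stop when the monitored loss has not improved for `patience` epochs.

    "Improved" means strictly lower than the best value seen so far.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.stale = 0

    def update(self, epoch: int, loss: float) -> bool:
        """Record one epoch; return True when training should stop."""
        if loss < self.best:
            self.best = loss
            self.best_epoch = epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


# ---------------------------------------------------------------------------
# layers


class _ConvBnRelu:
    def __init__(self, cin, cout, k, stride, rng, name):
        fan_in = cin * k * k
        self.w = nn.Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin, k, k)))
        self.gamma = nn.Parameter(np.ones(cout))
        self.beta = nn.Parameter(np.zeros(cout))
        self.running = {"mean": np.zeros(cout, np.float32), "var": np.ones(cout, np.float32)}
        self.k, self.stride, self.pad = k, stride, k // 2
        self.name = name

    def __call__(self, x, training):
        x = nn.conv2d(x, self.w, stride=self.stride, pad=self.pad)
        x = nn.batch_norm(x, self.gamma, self.beta, self.running, training)
        return nn.relu(x)

    def params(self):
        return {f"{self.name}.w": self.w, f"{self.name}.gamma": self.gamma, f"{self.name}.beta": self.beta}


class _BasicBlock:
    """ResNet basic unit: two 3×3 conv+BN with an identity shortcut."""

    def __init__(self, cin, cout, stride, rng, name):
        self.c1 = _ConvBnRelu(cin, cout, 3, stride, rng, f"{name}.conv1")
        # second conv: BN without the trailing ReLU (applied after the add)
        fan_in = cout * 9
        self.w2 = nn.Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cout, 3, 3)))
        self.gamma2 = nn.Parameter(np.ones(cout))
        self.beta2 = nn.Parameter(np.zeros(cout))
        self.running2 = {"mean": np.zeros(cout, np.float32), "var": np.ones(cout, np.float32)}
        self.proj = None
        if stride != 1 or cin != cout:
            self.wp = nn.Parameter(rng.normal(0.0, np.sqrt(2.0 / cin), (cout, cin, 1, 1)))
            self.gammap = nn.Parameter(np.ones(cout))
            self.betap = nn.Parameter(np.zeros(cout))
            self.runningp = {"mean": np.zeros(cout, np.float32), "var": np.ones(cout, np.float32)}
            self.proj = stride
        self.name = name

    def __call__(self, x, training):
        h = self.c1(x, training)
        h = nn.conv2d(h, self.w2, stride=1, pad=1)
        h = nn.batch_norm(h, self.gamma2, self.beta2, self.running2, training)
        if self.proj is not None:
            sc = nn.conv2d(x, self.wp, stride=self.proj, pad=0)
            sc = nn.batch_norm(sc, self.gammap, self.betap, self.runningp, training)
        else:
            sc = x
        return nn.relu(nn.add(h, sc))

    def params(self):
        out = dict(self.c1.params())
        out.update({f"{self.name}.w2": self.w2, f"{self.name}.gamma2": self.gamma2,
                    f"{self.name}.beta2": self.beta2})
        if self.proj is not None:
            out.update({f"{self.name}.wp": self.wp, f"{self.name}.gammap": self.gammap,
                        f"{self.name}.betap": self.betap})
        return out

    def runnings(self):
        out = {f"{self.name}.conv1": self.c1.running, f"{self.name}.bn2": self.running2}
        if self.proj is not None:
            out[f"{self.name}.bnp"] = self.runningp
        return out


class UrNet:
    """The assembled segmentation network. Build via :func:`build_urnet`."""

    def __init__(self, cfg: UrNetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        w = cfg.widths
        b = cfg.blocks_per_stage
        self.stem = _ConvBnRelu(cfg.in_channels, w[0], 7, 2, rng, "stem")
        self.stages = []
        cin = w[0]
        for si, cout in enumerate(w):
            stride0 = 1 if si == 0 else 2
            blocks = []
            for bi in range(b):
                blocks.append(
                    _BasicBlock(cin if bi == 0 else cout, cout,
                                stride0 if bi == 0 else 1, rng, f"enc{si + 1}.b{bi + 1}")
                )
            self.stages.append(blocks)
            cin = cout
        # decoder levels: 1/16 -> 1/8 -> 1/4 -> 1/2, each concatenating the
        # same-resolution encoder output (stages 3, 2, 1)
        self.dec = []
        dec_in = [w[3] + w[2], w[2] + w[1], w[1] + w[0]]
        dec_out = [w[2], w[1], w[0]]
        for di, (ci, co) in enumerate(zip(dec_in, dec_out)):
            self.dec.append(
                (
                    _ConvBnRelu(ci, co, 3, 1, rng, f"dec{di + 1}.conv1"),
                    _ConvBnRelu(co, co, 3, 1, rng, f"dec{di + 1}.conv2"),
                )
            )
        # final full-resolution level (no encoder skip at 1/1)
        self.final1 = _ConvBnRelu(w[0], max(2, w[0] // 2), 3, 1, rng, "final.conv1")
        fo = max(2, w[0] // 2)
        self.head_w = nn.Parameter(rng.normal(0.0, np.sqrt(2.0 / fo), (cfg.num_classes, fo, 1, 1)))
        self.head_b = nn.Parameter(np.zeros(cfg.num_classes))
        self._dropout_rng = np.random.default_rng(seed + 1)

    # -- forward ----------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> nn.Tensor:
        """x: (B, side, side, 3) normalized floats → (B, C, side, side) logits."""
        t = nn.Tensor(np.ascontiguousarray(x.transpose(0, 3, 1, 2), dtype=np.float32))
        h = self.stem(t, training)
        skips = []
        for blocks in self.stages:
            for blk in blocks:
                h = blk(h, training)
            skips.append(h)
        h = nn.dropout(skips[-1], self.cfg.dropout_rate, self._dropout_rng, training)
        for (c1, c2), skip in zip(self.dec, (skips[2], skips[1], skips[0])):
            h = nn.upsample_bilinear2x(h)
            h = nn.concat(h, skip)
            h = c2(c1(h, training), training)
        h = nn.upsample_bilinear2x(h)
        h = self.final1(h, training)
        return nn.conv2d(h, self.head_w, self.head_b, stride=1, pad=0)

    def logits(self, x: np.ndarray) -> np.ndarray:
        """Eval-mode class scores as (B, side, side, C)."""
        return self.forward(x, training=False).data.transpose(0, 2, 3, 1)

    # -- parameter bookkeeping --------------------------------------------
    def named_parameters(self) -> dict:
        out = dict(self.stem.params())
        for blocks in self.stages:
            for blk in blocks:
                out.update(blk.params())
        for c1, c2 in self.dec:
            out.update(c1.params())
            out.update(c2.params())
        out.update(self.final1.params())
        out["head.w"] = self.head_w
        out["head.b"] = self.head_b
        return out

    def parameters(self):
        return list(self.named_parameters().values())

    def num_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def _named_runnings(self) -> dict:
        out = {"stem": self.stem.running}
        for blocks in self.stages:
            for blk in blocks:
                out.update(blk.runnings())
        for c1, c2 in self.dec:
            out[c1.name] = c1.running
            out[c2.name] = c2.running
        out[self.final1.name] = self.final1.running
        return out

    def state_dict(self) -> dict:
        params = {k: p.data.copy() for k, p in self.named_parameters().items()}
        buffers = {}
        for name, running in self._named_runnings().items():
            buffers[f"{name}.running_mean"] = running["mean"].copy()
            buffers[f"{name}.running_var"] = running["var"].copy()
        return {"config": self.cfg.to_dict(), "params": params, "buffers": buffers}

    def load_state_dict(self, state: dict) -> None:
        named = self.named_parameters()
        for k, v in state["params"].items():
            named[k].data = np.asarray(v, dtype=np.float32).copy()
        runnings = self._named_runnings()
        for k, v in state.get("buffers", {}).items():
            name, kind = k.rsplit(".running_", 1)
            runnings[name]["mean" if kind == "mean" else "var"] = np.asarray(
                v, dtype=np.float32
            ).copy()

    # -- introspection -----------------------------------------------------
    def architecture_table(self) -> list[dict]:
        """Per-layer listing: name, kernel shape, stride, resolution factor.

        Parameter counts derivable from the kernel shapes sum to
        :meth:`num_params`, so the table doubles as an audit trail for the
        encoder/decoder layout.
        """
        rows = []
        for name, p in self.named_parameters().items():
            rows.append({"name": name, "shape": tuple(p.data.shape), "size": int(p.data.size)})
        return rows


def build_urnet(cfg: UrNetConfig | None = None, seed: int = 0) -> UrNet:
    """Construct a randomly initialized UrNet (no pretrained weights)."""
    return UrNet(cfg or UrNetConfig(), seed=seed)


# ---------------------------------------------------------------------------
# training


def _as_batch(pairs, idx):
    xs = np.stack([np.asarray(pairs[i][0].pixels, dtype=np.float32) for i in idx])
    ys = np.stack([pairs[i][1].labels.astype(np.int64) for i in idx])
    return xs, ys


def _epoch_loss(model, pairs, batch_size):
    """Eval-mode mean loss over a dataset (used for validation monitoring)."""
    total, npx = 0.0, 0
    for start in range(0, len(pairs), batch_size):
        idx = range(start, min(start + batch_size, len(pairs)))
        xs, ys = _as_batch(pairs, idx)
        logits = model.forward(xs, training=False)
        loss = nn.softmax_cross_entropy(logits, ys)
        total += float(loss.data) * ys.size
        npx += ys.size
    return total / npx


def train(model: UrNet, train_pairs, val_pairs=None, tcfg: TrainConfig | None = None):
    """Train a UrNet; returns ``(model, TrainHistory)``.

    Each epoch shuffles the training pairs, then for every batch runs
    forward, cross-entropy backward and one Adam step at the scheduled
    learning rate. Early stopping monitors the training loss by default
    (``tcfg.monitor='val'`` switches to validation loss) and the weights of
    the best-loss epoch are restored before returning.
    """
    tcfg = tcfg or TrainConfig()
    if not train_pairs:
        raise ValueError("training set is empty")
    if tcfg.monitor == "val" and not val_pairs:
        raise ValueError("monitor='val' requires a validation set")
    rng = np.random.default_rng(tcfg.seed)
    opt = nn.Adam(model.parameters(), lr=tcfg.lr0)
    stopper = EarlyStopping(tcfg.patience)
    history = TrainHistory()
    best_state = model.state_dict()
    step = 0
    for epoch in range(1, tcfg.max_epochs + 1):
        order = rng.permutation(len(train_pairs))
        ep_loss, ep_pix = 0.0, 0
        for start in range(0, len(order), tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            xs, ys = _as_batch(train_pairs, idx)
            logits = model.forward(xs, training=True)
            loss = nn.softmax_cross_entropy(logits, ys)
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step(lr=lr_schedule(tcfg.lr0, tcfg.decay, step))
            step += 1
            ep_loss += float(loss.data) * ys.size
            ep_pix += ys.size
        train_loss = ep_loss / ep_pix
        val_loss = _epoch_loss(model, val_pairs, tcfg.batch_size) if val_pairs else None
        history.epochs.append(
            {"epoch": epoch, "loss": train_loss, "val_loss": val_loss,
             "lr": lr_schedule(tcfg.lr0, tcfg.decay, step - 1)}
        )
        monitored = train_loss if tcfg.monitor == "train" else val_loss
        improved = monitored < stopper.best
        should_stop = stopper.update(epoch, monitored)
        if improved:
            best_state = model.state_dict()
        if should_stop:
            history.stop_reason = "early_stop"
            history.stop_epoch = epoch
            break
    else:
        history.stop_reason = "max_epochs"
        history.stop_epoch = tcfg.max_epochs
    model.load_state_dict(best_state)
    return model, history


def predict_mask(model: UrNet, img: RgbImage) -> SegMask:
    """Coarse segmentation: per-pixel argmax of the two class scores.

    Exact ties go to background, so an untrained all-zero head yields an
    all-background mask rather than an arbitrary one.
    """
    if img.value_range != NORMALIZED:
        raise ValueError("predict_mask expects a normalized image")
    if img.height != img.width:
        raise ValueError("predict_mask expects a square (canonical) image")
    scores = model.logits(img.pixels[None])[0]  # (H, W, C)
    return SegMask((scores[..., 1] > scores[..., 0]).astype(np.uint8))
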