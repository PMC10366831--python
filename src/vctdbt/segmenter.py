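"""Compact 3D U-Net segmenter with a pure-numpy trainer.

The network is a small encoder-decoder with skip connections: one
3x3x3 convolution + instance normalization + leaky ReLU per resolution
level, 2x average pooling, nearest-neighbour upsampling, and a final
1x1x1 convolution to three class logits (air / adipose / dense).
Instance normalization and leaky activations follow the reference
full-resolution 3D U-Net design and keep training stable at the
protocol's aggressive learning rate.  Convolutions are evaluated as
im2col matrix products and gradients are propagated analytically, so
training needs no GPU framework; the focal-Tversky losses in
:mod:`vctdbt.loss` supply dL/dp.

The training protocol follows the study design: Adam with learning rate
0.01, batch size 2, checkpoints every five epochs with the best
validation-Dice snapshot retained, and an 80/20 train/validation split by
phantom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .loss import LossConfig, combined_loss_grad, one_hot
from .phantom import LabelVolume
from .reconstructor import ReconVolume


@dataclass(frozen=True)
class UNetConfig:
    depth: int = 2                 # number of 2x poolings
    base_channels: int = 8
    n_classes: int = 3
    in_channels: int = 1
    patch_size: int | None = None  # None => whole-volume inference
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_classes != 3:
            raise ValueError("this segmenter is three-class")
        if self.patch_size is not None and self.patch_size % (2 ** self.depth):
            raise ValueError("patch_size must be divisible by 2**depth")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.01
    batch_size: int = 2
    checkpoint_every: int = 5
    max_epochs: int = 20
    seed: int = 0
    val_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


# ---------------------------------------------------------------------------
# layer primitives (channel-first arrays (C, D, H, W), float32)
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray) -> np.ndarray:
    """(C, D+2, H+2, W+2) padded input -> (N, C*27) patch matrix."""
    c = xp.shape[0]
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3, 3),
                                                   axis=(1, 2, 3))
    # win: (C, D, H, W, 3, 3, 3) -> (D, H, W, C, 27) -> (N, C*27)
    d, h, w = win.shape[1:4]
    return win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(d * h * w, c * 27)


def _conv3(x: np.ndarray, w: np.ndarray, b: np.ndarray,
           return_cols: bool = False):
    """Same-size 3x3x3 convolution; w is (Cout, Cin, 3, 3, 3)."""
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    cols = _im2col(xp)
    cout = w.shape[0]
    y = cols @ w.reshape(cout, -1).T + b
    d, h, wd = x.shape[1:]
    y = np.ascontiguousarray(y.reshape(d, h, wd, cout).transpose(3, 0, 1, 2))
    return (y, cols) if return_cols else y


def _conv3_backward(cols: np.ndarray, shape: tuple, w: np.ndarray,
                    dy: np.ndarray, need_dx: bool = True):
    """Gradients of _conv3 given its cached patch matrix.

    ``cols`` is the (N, Cin*27) im2col matrix of the forward input and
    ``shape`` its (Cin, D, H, W) shape; returns (dx, dw, db) with dx None
    when ``need_dx`` is false.
    """
    cout, cin = w.shape[:2]
    d, h, wd = shape[1:]
    dy_mat = dy.transpose(1, 2, 3, 0).reshape(-1, cout)  # (N, Cout)
    dw = (dy_mat.T @ cols).reshape(w.shape)
    db = dy_mat.sum(axis=0)
    if not need_dx:
        return None, dw, db
    # dx: correlate dy with spatially flipped kernels, channels swapped
    w_flip = w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)  # (Cin, Cout,3,3,3)
    dyp = np.pad(dy, ((0, 0), (1, 1), (1, 1), (1, 1)))
    dcols = _im2col(dyp)
    dx = dcols @ np.ascontiguousarray(w_flip.reshape(cin, -1)).T
    dx = np.ascontiguousarray(dx.reshape(d, h, wd, cin).transpose(3, 0, 1, 2))
    return dx, dw, db


def _conv1(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """1x1x1 convolution; w is (Cout, Cin)."""
    return np.einsum("oc,cdhw->odhw", w, x) + b[:, None, None, None]


def _avgpool2(x: np.ndarray) -> np.ndarray:
    c, d, h, w = x.shape
    return x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(2, 4, 6))


def _avgpool2_backward(dy: np.ndarray) -> np.ndarray:
    up = dy / 8.0
    for ax in (1, 2, 3):
        up = np.repeat(up, 2, axis=ax)
    return up


def _upsample2(x: np.ndarray) -> np.ndarray:
    for ax in (1, 2, 3):
        x = np.repeat(x, 2, axis=ax)
    return x


def _upsample2_backward(dy: np.ndarray) -> np.ndarray:
    c, d, h, w = dy.shape
    return dy.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(2, 4, 6))


_LEAKY_SLOPE = 0.01
_IN_EPS = 1e-5


def _instnorm(z: np.ndarray, gamma: np.ndarray, beta: np.ndarray):
    """Instance normalization over the spatial dims of (C, D, H, W)."""
    mu = z.mean(axis=(1, 2, 3), keepdims=True)
    var = z.var(axis=(1, 2, 3), keepdims=True)
    sig = np.sqrt(var + _IN_EPS)
    xhat = (z - mu) / sig
    return gamma[:, None, None, None] * xhat + beta[:, None, None, None], xhat, sig


def _instnorm_backward(dy: np.ndarray, xhat: np.ndarray, sig: np.ndarray,
                       gamma: np.ndarray):
    dgamma = (dy * xhat).sum(axis=(1, 2, 3))
    dbeta = dy.sum(axis=(1, 2, 3))
    dxhat = dy * gamma[:, None, None, None]
    m1 = dxhat.mean(axis=(1, 2, 3), keepdims=True)
    m2 = (dxhat * xhat).mean(axis=(1, 2, 3), keepdims=True)
    dz = (dxhat - m1 - xhat * m2) / sig
    return dz, dgamma, dbeta


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


class UNet3D:
    """Parameter container + forward/backward passes."""

    def __init__(self, config: UNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        ch_in = config.in_channels
        enc_ch = []
        for lvl in range(config.depth + 1):           # encoder + bottleneck
            ch_out = config.base_channels * 2 ** lvl
            self._add_conv(rng, f"enc{lvl}", ch_in, ch_out)
            enc_ch.append(ch_out)
            ch_in = ch_out
        for lvl in range(config.depth - 1, -1, -1):   # decoder
            skip = enc_ch[lvl]
            self._add_conv(rng, f"dec{lvl}", ch_in + skip, skip)
            ch_in = skip
        w = rng.normal(0.0, np.sqrt(2.0 / ch_in),
                       (config.n_classes, ch_in)).astype(np.float32)
        self.params["head_w"] = w
        self.params["head_b"] = np.zeros(config.n_classes, dtype=np.float32)

    def _add_conv(self, rng, name: str, cin: int, cout: int) -> None:
        std = np.sqrt(2.0 / (cin * 27))
        self.params[f"{name}_w"] = rng.normal(0.0, std,
                                              (cout, cin, 3, 3, 3)).astype(np.float32)
        self.params[f"{name}_b"] = np.zeros(cout, dtype=np.float32)
        self.params[f"{name}_g"] = np.ones(cout, dtype=np.float32)
        self.params[f"{name}_s"] = np.zeros(cout, dtype=np.float32)

    def _block(self, h: np.ndarray, name: str, cache: dict | None):
        """conv3 -> instance norm -> leaky ReLU."""
        p = self.params
        shape = h.shape
        z, cols = _conv3(h, p[f"{name}_w"], p[f"{name}_b"], return_cols=True)
        y, xhat, sig = _instnorm(z, p[f"{name}_g"], p[f"{name}_s"])
        mask = y > 0
        out = np.where(mask, y, _LEAKY_SLOPE * y)
        if cache is not None:
            cache[name] = {"cols": cols, "shape": shape, "xhat": xhat,
                           "sig": sig, "mask": mask}
        return out

    def _block_backward(self, dh: np.ndarray, name: str, cache: dict,
                        grads: dict, need_dx: bool = True):
        p = self.params
        c = cache[name]
        dh = np.where(c["mask"], dh, _LEAKY_SLOPE * dh)
        dz, dgamma, dbeta = _instnorm_backward(dh, c["xhat"], c["sig"],
                                               p[f"{name}_g"])
        grads[f"{name}_g"] = dgamma
        grads[f"{name}_s"] = dbeta
        dx, dw, db = _conv3_backward(c["cols"], c["shape"], p[f"{name}_w"],
                                     dz.astype(np.float32), need_dx=need_dx)
        grads[f"{name}_w"] = dw
        grads[f"{name}_b"] = db
        return dx

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (in_channels, D, H, W) with dims divisible by 2**depth."""
        p, cfg = self.params, self.config
        cache: dict = {} if want_cache else None
        feats = []
        h = x
        for lvl in range(cfg.depth + 1):
            h = self._block(h, f"enc{lvl}", cache)
            if lvl < cfg.depth:
                feats.append(h)
                h = _avgpool2(h)
        for lvl in range(cfg.depth - 1, -1, -1):
            h = np.concatenate([_upsample2(h), feats[lvl]], axis=0)
            h = self._block(h, f"dec{lvl}", cache)
        logits = _conv1(h, p["head_w"], p["head_b"])
        if want_cache:
            cache["pre_head"] = h
            return logits, cache
        return logits

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        p, cfg = self.params, self.config
        grads: dict[str, np.ndarray] = {}
        h = cache["pre_head"]
        grads["head_w"] = np.einsum("odhw,cdhw->oc", dlogits, h)
        grads["head_b"] = dlogits.sum(axis=(1, 2, 3))
        dh = np.einsum("oc,odhw->cdhw", p["head_w"], dlogits)

        dskips: dict[int, np.ndarray] = {}
        for lvl in range(0, cfg.depth):
            dh = self._block_backward(dh, f"dec{lvl}", cache, grads)
            skip_ch = p[f"enc{lvl}_w"].shape[0]
            up_ch = cache[f"dec{lvl}"]["shape"][0] - skip_ch
            dskips[lvl] = dh[up_ch:]
            dh = _upsample2_backward(dh[:up_ch])

        for lvl in range(cfg.depth, -1, -1):
            if lvl < cfg.depth:
                dh = _avgpool2_backward(dh) + dskips[lvl]
            dh = self._block_backward(dh, f"enc{lvl}", cache, grads,
                                      need_dx=lvl > 0)
        return grads

    def state_copy(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in state.items()}

    def save(self, path) -> None:
        import json
        from dataclasses import asdict
        np.savez(str(path), __config__=json.dumps(asdict(self.config)),
                 **self.params)

    @classmethod
    def load(cls, path) -> "UNet3D":
        import json
        data = np.load(str(path), allow_pickle=False)
        cfg = UNetConfig(**json.loads(str(data["__config__"])))
        model = cls(cfg)
        model.params = {k: data[k] for k in data.files if k != "__config__"}
        return model


class _Adam:
    def __init__(self, params: dict, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k in params:
            g = grads[k].astype(np.float32)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------

def _pad_to_multiple(x: np.ndarray, m: int) -> tuple[np.ndarray, tuple]:
    """Zero-pad trailing spatial dims of (C, D, H, W) up to multiples of m."""
    shape = x.shape[1:]
    pads = [(0, (m - s % m) % m) for s in shape]
    xp = np.pad(x, [(0, 0)] + pads)
    return xp, tuple(shape)


def _prepare_input(recon: ReconVolume) -> np.ndarray:
    """Per-volume z-scored reconstruction as a 1-channel float32 array."""
    v = recon.values.astype(np.float32)
    std = float(v.std())
    v = (v - v.mean()) / (std if std > 0 else 1.0)
    return v[None]


def _hard_dice(pred_labels: np.ndarray, truth_labels: np.ndarray,
               n_classes: int = 3) -> list[float]:
    out = []
    for c in range(n_classes):
        a = pred_labels == c
        b = truth_labels == c
        denom = a.sum() + b.sum()
        out.append(float(2.0 * (a & b).sum() / denom) if denom else float("nan"))
    return out


def _loss_and_dlogits(logits: np.ndarray, g: np.ndarray,
                      loss_cfg: LossConfig) -> tuple[float, np.ndarray]:
    prob = _softmax(logits.astype(np.float64))
    value, dprob = combined_loss_grad(prob, g, loss_cfg)
    # softmax backward: dz_c = p_c (dp_c - sum_k p_k dp_k)
    inner = (prob * dprob).sum(axis=0, keepdims=True)
    dlogits = prob * (dprob - inner)
    return value, dlogits.astype(np.float32)


def train(samples, loss_cfg: LossConfig | None = None,
          unet_cfg: UNetConfig | None = None,
          train_cfg: TrainConfig | None = None):
    """Train a U-Net on (recon, mask) samples; returns (model, history).

    ``samples`` is a sequence with ``recon`` (ReconVolume) and ``mask``
    (LabelVolume) attributes on congruent grids.  History holds one record
    per epoch (train loss, validation loss, per-class validation Dice).
    Every ``checkpoint_every`` epochs the model is evaluated and the best
    validation-Dice snapshot is retained as the returned model.
    """
    loss_cfg = loss_cfg or LossConfig()
    unet_cfg = unet_cfg or UNetConfig()
    train_cfg = train_cfg or TrainConfig()
    samples = list(samples)
    if not samples:
        raise ValueError("no training samples")
    for s in samples:
        if s.recon.shape != s.mask.shape:
            raise ValueError("recon and mask grids must be congruent")

    rng = np.random.default_rng(train_cfg.seed)
    mult = 2 ** unet_cfg.depth
    prepared = []
    for s in samples:
        x, _ = _pad_to_multiple(_prepare_input(s.recon), mult)
        g, _ = _pad_to_multiple(one_hot(s.mask.labels), mult)
        prepared.append((x.astype(np.float32), g.astype(np.float32),
                         s.mask.labels))

    n = len(prepared)
    order = rng.permutation(n)
    if n >= 2:
        n_val = max(1, int(round(train_cfg.val_fraction * n)))
        val_idx, train_idx = order[:n_val], order[n_val:]
        if len(train_idx) == 0:
            train_idx = val_idx
    else:
        val_idx = train_idx = order

    model = UNet3D(UNetConfig(**{**unet_cfg.__dict__, "seed": train_cfg.seed}))
    opt = _Adam(model.params, train_cfg.learning_rate)

    def _evaluate() -> tuple[float, list[float]]:
        losses, dices = [], []
        for i in val_idx:
            x, g, labels = prepared[i]
            logits = model.forward(x)
            value, _ = _loss_and_dlogits(logits, g, loss_cfg)
            losses.append(value)
            crop = tuple(slice(0, s) for s in labels.shape)
            pred = np.argmax(logits, axis=0)[crop]
            dices.append(_hard_dice(pred, labels))
        return float(np.mean(losses)), list(np.nanmean(dices, axis=0))

    history: list[dict] = []
    best_state = model.state_copy()
    best_dice = -np.inf
    for epoch in range(1, train_cfg.max_epochs + 1):
        perm = rng.permutation(len(train_idx))
        epoch_losses = []
        for b0 in range(0, len(perm), train_cfg.batch_size):
            batch = [train_idx[j] for j in perm[b0:b0 + train_cfg.batch_size]]
            grads_acc = None
            for i in batch:
                x, g, _ = prepared[i]
                logits, cache = model.forward(x, want_cache=True)
                value, dlogits = _loss_and_dlogits(logits, g, loss_cfg)
                grads = model.backward(cache, dlogits)
                epoch_losses.append(value)
                if grads_acc is None:
                    grads_acc = grads
                else:
                    for k in grads_acc:
                        grads_acc[k] += grads[k]
            for k in grads_acc:
                grads_acc[k] /= len(batch)
            opt.step(model.params, grads_acc)

        val_loss, val_dice = _evaluate()
        history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": val_loss,
            "val_dice_air": val_dice[0],
            "val_dice_adipose": val_dice[1],
            "val_dice_dense": val_dice[2],
        })
        if epoch % train_cfg.checkpoint_every == 0 or epoch == train_cfg.max_epochs:
            mean_dice = float(np.nanmean(val_dice))
            if mean_dice > best_dice:
                best_dice = mean_dice
                best_state = model.state_copy()
    model.load_state(best_state)
    return model, history


def predict(model: UNet3D, recon: ReconVolume) -> np.ndarray:
    """Per-voxel class probability map (3, nx, ny, nz), summing to 1.

    Whole-volume inference by default; if the model's ``patch_size`` is set
    and smaller than the volume, overlapping patches (50% stride) are
    blended by averaging.
    """
    mult = 2 ** model.config.depth
    x, orig = _pad_to_multiple(_prepare_input(recon), mult)
    ps = model.config.patch_size
    if ps is None or all(s <= ps for s in x.shape[1:]):
        logits = model.forward(x)
        prob = _softmax(logits.astype(np.float64))
    else:
        prob_acc = np.zeros((model.config.n_classes,) + x.shape[1:])
        weight = np.zeros(x.shape[1:])
        step = ps // 2
        starts = []
        for s in x.shape[1:]:
            last = max(s - ps, 0)
            pos = sorted(set(list(range(0, last + 1, step)) + [last]))
            starts.append(pos)
        for d0 in starts[0]:
            for h0 in starts[1]:
                for w0 in starts[2]:
                    sl = (slice(d0, d0 + ps), slice(h0, h0 + ps),
                          slice(w0, w0 + ps))
                    patch = x[(slice(None),) + sl]
                    pp, pad_shape = _pad_to_multiple(patch, mult)
                    logits = model.forward(pp)
                    crop = tuple(slice(0, s) for s in patch.shape[1:])
                    prob_acc[(slice(None),) + sl] += _softmax(
                        logits.astype(np.float64))[(slice(None),) + crop]
                    weight[sl] += 1.0
        prob = prob_acc / weight[None]
    crop = tuple(slice(0, s) for s in orig)
    prob = prob[(slice(None),) + crop]
    return prob / prob.sum(axis=0, keepdims=True)


def argmax_labels(prob: np.ndarray, voxel_mm: float = 1.0) -> LabelVolume:
    """Per-voxel argmax; ties break toward the lower class index."""
    if prob.ndim != 4:
        raise ValueError("probability map must be (C, nx, ny, nz)")
    return LabelVolume(labels=np.argmax(prob, axis=0).astype(np.uint8),
                       voxel_mm=voxel_mm)
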