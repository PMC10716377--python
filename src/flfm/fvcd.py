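"""The two-stage F-VCD model: view-correlated denoising + view-to-depth
reconstruction.

Stage 1, **F-Denoise**, is a residual-channel-attention (RCAN-style)
denoiser over the three light-field views with an extra *view-attention*
branch: a squeeze-excite gate over the view axis that reweights whole
views before the trunk, compensating the per-view differences in SNR and
resolution that parallax introduces.  Stage 2, **F-Reconstruction**,
expands the three views through three dilated-convolution blocks
(rates 1/2/4) into a multi-scale feature stack, then maps features to
the 41-plane depth stack through a small U-Net whose encoder blocks are
residual blocks with instance normalization and leaky rectifiers, with
optional sub-pixel (pixel-shuffle) lateral upscaling.

Training follows a pretrain-then-joint schedule: each sub-net is first
pretrained against its own ground truth (clean views for the denoiser,
the HR stack for the reconstructor), then both are optimized jointly
under the weighted loss 0.2 * denoise + 0.8 * reconstruction, with Adam
and an exponentially decaying learning rate.  The denoise loss is a
weighted L1-L2 mix; the reconstruction loss is L2 plus a
finite-difference gradient term that protects high-frequency detail.
The best-on-validation parameters are kept for inference.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .forward import Volume
from .geometry import CalibrationResult, LFImage, ViewStack, extract_views
from .nn import (Adam, ChannelAttention, Conv2d, InstanceNorm2d, LeakyReLU,
                 Module, PixelShuffle, Residual, Sequential)


class TrainingDivergence(RuntimeError):
    def __init__(self, step: int):
        super().__init__(f"training diverged (non-finite loss) at step {step}")
        self.step = step


# ---------------------------------------------------------------------------
# Specs / config
# ---------------------------------------------------------------------------

@dataclass
class DenoiseNetSpec:
    n_residual_groups: int = 1
    n_channel_attention_blocks: int = 2
    feature_width: int = 8
    reduction: int = 2
    view_attention: bool = True
    lrelu_slope: float = 0.1

    def to_dict(self):
        return dict(self.__dict__)


@dataclass
class ReconNetSpec:
    dilation_rates: tuple[int, int, int] = (1, 2, 4)
    dilation_widths: tuple[int, int, int] = (8, 12, 16)
    unet_width: int = 16
    upscale: int = 1
    n_depths: int = 41
    normalization: str = "instance"        # instance | none
    lrelu_slope: float = 0.1

    def to_dict(self):
        d = dict(self.__dict__)
        d["dilation_rates"] = list(self.dilation_rates)
        d["dilation_widths"] = list(self.dilation_widths)
        return d


@dataclass
class TrainingConfig:
    denoise_loss_weight: float = 0.2
    recon_loss_weight: float = 0.8
    l1_fraction: float = 0.5               # alpha in the L1-L2 denoise loss
    gradient_loss_weight: float = 0.1      # beta in the reconstruction loss
    learning_rate: float = 1e-3
    lr_decay: float = 0.97                 # per epoch
    epochs: int = 30
    batch_size: int = 4
    pretrain_patch: tuple[int, int, int] = (160, 160, 3)
    joint_patch: tuple[int, int, int] = (80, 80, 3)
    validation_fraction: float = 0.25
    checkpoint_metric: str = "ssim"        # ssim (max) | loss (min)
    seed: int = 0

    def __post_init__(self):
        if abs(self.denoise_loss_weight + self.recon_loss_weight - 1.0) > 1e-9:
            raise ValueError("denoise and reconstruction loss weights must "
                             "sum to 1")
        if self.pretrain_patch[2] != 3 or self.joint_patch[2] != 3:
            raise ValueError("patches must carry 3 views")


# ---------------------------------------------------------------------------
# Losses (value + analytic gradient w.r.t. prediction)
# ---------------------------------------------------------------------------

def denoise_loss(pred: np.ndarray, gt: np.ndarray, alpha: float = 0.5,
                 with_grad: bool = False):
    """Weighted L1-L2: alpha * mean|d| + (1 - alpha) * mean d^2."""
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    d = pred - gt
    loss = alpha * np.mean(np.abs(d)) + (1 - alpha) * np.mean(d**2)
    if not with_grad:
        return float(loss)
    grad = (alpha * np.sign(d) + 2 * (1 - alpha) * d) / d.size
    return float(loss), grad


def recon_loss(pred: np.ndarray, gt: np.ndarray, beta: float = 0.1,
               with_grad: bool = False):
    """L2 + gradient loss.

    MSE plus ``beta`` times the average (over the spatial axes) of the
    mean squared difference of forward finite-difference gradients:

        L = mean d^2 + beta * (1/A) * sum_axes mean (diff_a(pred) - diff_a(gt))^2

    where the axes are the trailing (z, y, x) axes of the stack.
    """
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    d = pred - gt
    loss = np.mean(d**2)
    grad = 2 * d / d.size if with_grad else None
    axes = list(range(pred.ndim - 3, pred.ndim))
    for ax in axes:
        dd = np.diff(d, axis=ax)
        if dd.size == 0:        # singleton axis: no gradient content
            continue
        loss = loss + beta * np.mean(dd**2) / len(axes)
        if with_grad:
            e = 2 * dd / dd.size * (beta / len(axes))
            pad_lo = [slice(None)] * pred.ndim
            pad_hi = [slice(None)] * pred.ndim
            pad_lo[ax] = slice(0, -1)
            pad_hi[ax] = slice(1, None)
            grad[tuple(pad_lo)] -= e
            grad[tuple(pad_hi)] += e
    if not with_grad:
        return float(loss)
    return float(loss), grad


def joint_loss(denoise_term: float, recon_term: float,
               cfg: TrainingConfig | None = None) -> float:
    """Weighted two-stage loss, 0.2 * denoise + 0.8 * reconstruction."""
    cfg = cfg or TrainingConfig()
    return (cfg.denoise_loss_weight * denoise_term
            + cfg.recon_loss_weight * recon_term)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

def _cab(c: int, reduction: int, slope: float, rng) -> Module:
    """Residual channel-attention block."""
    return Residual(Sequential(
        Conv2d(c, c, 3, rng=rng), LeakyReLU(slope),
        Conv2d(c, c, 3, rng=rng), ChannelAttention(c, reduction, rng=rng)))


class FDenoise(Module):
    """RCAN-style view denoiser with a view-attention input gate.

    Maps (B, 3, h, w) noisy views to denoised views of the same shape
    through a global-residual trunk; with ``view_attention`` disabled
    the model is a plain RCAN (the gate parameters are simply absent).
    """

    def __init__(self, spec: DenoiseNetSpec | None = None, seed: int = 0):
        self.spec = spec or DenoiseNetSpec()
        rng = np.random.default_rng(seed)
        s = self.spec
        self.view_gate = (ChannelAttention(3, reduction=1, rng=rng)
                          if s.view_attention else None)
        groups = []
        for _ in range(s.n_residual_groups):
            blocks = [_cab(s.feature_width, s.reduction, s.lrelu_slope, rng)
                      for _ in range(s.n_channel_attention_blocks)]
            blocks.append(Conv2d(s.feature_width, s.feature_width, 3, rng=rng))
            groups.append(Residual(Sequential(*blocks)))
        self.trunk = Sequential(
            Conv2d(3, s.feature_width, 3, rng=rng),
            *groups,
            Conv2d(s.feature_width, 3, 3, rng=rng))

    def params(self):
        p = self.trunk.params()
        if self.view_gate is not None:
            p = self.view_gate.params() + p
        return p

    def forward(self, x, train=True):
        x0 = self.view_gate.forward(x, train) if self.view_gate else x
        return x + self.trunk.forward(x0, train=train)

    def backward(self, g):
        gt = self.trunk.backward(g)
        if self.view_gate is not None:
            gt = self.view_gate.backward(gt)
        return g + gt


class _ResBlock(Module):
    """conv-norm-act-conv-norm with a (projected) skip connection."""

    def __init__(self, cin: int, cout: int, norm: str, slope: float, rng):
        def n():
            return [InstanceNorm2d(cout)] if norm == "instance" else []
        self.body = Sequential(
            Conv2d(cin, cout, 3, rng=rng), *n(), LeakyReLU(slope),
            Conv2d(cout, cout, 3, rng=rng), *n())
        self.proj = Conv2d(cin, cout, 1, rng=rng) if cin != cout else None

    def params(self):
        p = self.body.params()
        if self.proj is not None:
            p += self.proj.params()
        return p

    def forward(self, x, train=True):
        skip = self.proj.forward(x, train) if self.proj else x
        return skip + self.body.forward(x, train=train)

    def backward(self, g):
        gb = self.body.backward(g)
        gs = self.proj.backward(g) if self.proj else g
        return gb + gs


class FRecon(Module):
    """Dilated multi-scale feature extraction + U-Net view-to-depth map.

    (B, 3, h, w) views -> (B, n_depths, h * upscale, w * upscale).
    """

    def __init__(self, spec: ReconNetSpec | None = None, seed: int = 0):
        self.spec = spec or ReconNetSpec()
        s = self.spec
        rng = np.random.default_rng(seed + 1)
        w1, w2, w3 = s.dilation_widths
        d1, d2, d3 = s.dilation_rates
        sl = s.lrelu_slope
        self.dilated = Sequential(
            Conv2d(3, w1, 3, dilation=d1, rng=rng), LeakyReLU(sl),
            Conv2d(w1, w2, 3, dilation=d2, rng=rng), LeakyReLU(sl),
            Conv2d(w2, w3, 3, dilation=d3, rng=rng), LeakyReLU(sl))
        f = s.unet_width
        from .nn import UpsampleNearest2
        # two-level encoder/decoder: the bottom level sees a receptive
        # field wide enough to cover the full parallax excursion
        self.enc1 = _ResBlock(w3, f, s.normalization, sl, rng)
        self.down1 = Sequential(Conv2d(f, 2 * f, 3, stride=2, rng=rng),
                                LeakyReLU(sl))
        self.enc2 = _ResBlock(2 * f, 2 * f, s.normalization, sl, rng)
        self.down2 = Sequential(Conv2d(2 * f, 4 * f, 3, stride=2, rng=rng),
                                LeakyReLU(sl))
        self.bottleneck = _ResBlock(4 * f, 4 * f, s.normalization, sl, rng)
        self.up2 = Sequential(UpsampleNearest2(),
                              Conv2d(4 * f, 2 * f, 3, rng=rng), LeakyReLU(sl))
        self.fuse2 = Sequential(Conv2d(4 * f, 2 * f, 3, rng=rng),
                                LeakyReLU(sl))
        self.up1 = Sequential(UpsampleNearest2(),
                              Conv2d(2 * f, f, 3, rng=rng), LeakyReLU(sl))
        self.fuse1 = Sequential(Conv2d(2 * f, f, 3, rng=rng), LeakyReLU(sl))
        self.dec = _ResBlock(f, f, s.normalization, sl, rng)
        self.head = Conv2d(f, s.n_depths * s.upscale**2, 3, rng=rng)
        self.shuffle = PixelShuffle(s.upscale) if s.upscale > 1 else None

    def params(self):
        mods = [self.dilated, self.enc1, self.down1, self.enc2, self.down2,
                self.bottleneck, self.up2, self.fuse2, self.up1, self.fuse1,
                self.dec, self.head]
        return [p for m in mods for p in m.params()]

    def forward(self, x, train=True):
        if x.shape[2] % 4 or x.shape[3] % 4:
            raise ValueError("input height/width must be divisible by 4")
        f0 = self.dilated.forward(x, train=train)
        e1 = self.enc1.forward(f0, train=train)
        e2 = self.enc2.forward(self.down1.forward(e1, train=train),
                               train=train)
        b = self.bottleneck.forward(self.down2.forward(e2, train=train),
                                    train=train)
        u2 = self.up2.forward(b, train=train)
        y2 = self.fuse2.forward(np.concatenate([e2, u2], axis=1), train=train)
        u1 = self.up1.forward(y2, train=train)
        y1 = self.fuse1.forward(np.concatenate([e1, u1], axis=1), train=train)
        y = self.dec.forward(y1, train=train)
        y = self.head.forward(y, train=train)
        if self.shuffle is not None:
            y = self.shuffle.forward(y, train=train)
        return y

    def backward(self, g):
        f = self.spec.unet_width
        if self.shuffle is not None:
            g = self.shuffle.backward(g)
        g = self.head.backward(g)
        g = self.dec.backward(g)
        gcat1 = self.fuse1.backward(g)
        ge1, gu1 = gcat1[:, :f], gcat1[:, f:]
        gy2 = self.up1.backward(gu1)
        gcat2 = self.fuse2.backward(gy2)
        ge2, gu2 = gcat2[:, :2 * f], gcat2[:, 2 * f:]
        gb = self.up2.backward(gu2)
        ge2 = ge2 + self.down2.backward(self.bottleneck.backward(gb))
        ge1 = ge1 + self.down1.backward(self.enc2.backward(ge2))
        gf0 = self.enc1.backward(ge1)
        return self.dilated.backward(gf0)


# ---------------------------------------------------------------------------
# Patch sampling
# ---------------------------------------------------------------------------

def sample_patch(views: np.ndarray, stack: np.ndarray | None,
                 patch: tuple[int, int, int], rng: np.random.Generator,
                 upscale: int = 1):
    """Random aligned crop from a (3, H, W) view stack and its HR stack.

    The requested patch is clipped (to an even size) when the source is
    smaller; the HR crop covers the same field at ``upscale`` times the
    lateral sampling.
    """
    ph = min(patch[0], views.shape[1])
    pw = min(patch[1], views.shape[2])
    ph -= ph % 2
    pw -= pw % 2
    r0 = int(rng.integers(0, views.shape[1] - ph + 1))
    c0 = int(rng.integers(0, views.shape[2] - pw + 1))
    v = views[:, r0:r0 + ph, c0:c0 + pw]
    if stack is None:
        return v, None
    s = stack[:, r0 * upscale:(r0 + ph) * upscale,
              c0 * upscale:(c0 + pw) * upscale]
    return v, s


def _batches(n: int, bs: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    for i in range(0, n, bs):
        yield idx[i:i + bs]


def select_best_epoch(metric_trace, mode: str = "max") -> int:
    """Index of the best validation metric (argmax/argmin contract)."""
    arr = np.asarray(metric_trace, dtype=float)
    return int(np.argmax(arr) if mode == "max" else np.argmin(arr))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _check_finite(loss: float, step: int):
    if not np.isfinite(loss):
        raise TrainingDivergence(step)


def pretrain_denoise(dataset, cfg: TrainingConfig,
                     spec: DenoiseNetSpec | None = None):
    """Pretrain F-Denoise on (noisy views -> clean views) patches."""
    if not dataset:
        raise ValueError("empty dataset")
    model = FDenoise(spec, seed=cfg.seed)
    opt = Adam(model.params(), lr=cfg.learning_rate, lr_decay=cfg.lr_decay)
    rng = np.random.default_rng(cfg.seed + 101)
    curve = []
    step = 0
    for _ in range(cfg.epochs):
        for batch in _batches(len(dataset), cfg.batch_size, rng):
            xs, ys = [], []
            for i in batch:
                t = dataset[i]
                vc, gc = _aligned_pair(t.noisy_views.data, t.clean_views.data,
                                       cfg.pretrain_patch, rng)
                xs.append(vc)
                ys.append(gc)
            x = np.stack(xs)
            y = np.stack(ys)
            pred = model.forward(x)
            loss, grad = denoise_loss(pred, y, alpha=cfg.l1_fraction,
                                      with_grad=True)
            _check_finite(loss, step)
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            curve.append(loss)
            step += 1
        opt.decay_epoch()
    return model, curve


def _aligned_pair(a: np.ndarray, b: np.ndarray, patch, rng):
    ph = min(patch[0], a.shape[1])
    pw = min(patch[1], a.shape[2])
    ph -= ph % 2
    pw -= pw % 2
    r0 = int(rng.integers(0, a.shape[1] - ph + 1))
    c0 = int(rng.integers(0, a.shape[2] - pw + 1))
    return (a[:, r0:r0 + ph, c0:c0 + pw], b[:, r0:r0 + ph, c0:c0 + pw])


def _aligned_volume_pair(views, stack, patch, rng, upscale):
    ph = min(patch[0], views.shape[1])
    pw = min(patch[1], views.shape[2])
    ph -= ph % 2
    pw -= pw % 2
    r0 = int(rng.integers(0, views.shape[1] - ph + 1))
    c0 = int(rng.integers(0, views.shape[2] - pw + 1))
    v = views[:, r0:r0 + ph, c0:c0 + pw]
    s = stack[:, r0 * upscale:(r0 + ph) * upscale,
              c0 * upscale:(c0 + pw) * upscale]
    return v, s


def pretrain_recon(dataset, cfg: TrainingConfig,
                   spec: ReconNetSpec | None = None):
    """Pretrain F-Reconstruction on (clean views -> HR stack) patches."""
    if not dataset:
        raise ValueError("empty dataset")
    model = FRecon(spec, seed=cfg.seed)
    upscale = model.spec.upscale
    opt = Adam(model.params(), lr=cfg.learning_rate, lr_decay=cfg.lr_decay)
    rng = np.random.default_rng(cfg.seed + 202)
    curve = []
    step = 0
    for _ in range(cfg.epochs):
        for batch in _batches(len(dataset), cfg.batch_size, rng):
            xs, ys = [], []
            for i in batch:
                t = dataset[i]
                v, s = _aligned_volume_pair(t.clean_views.data,
                                            t.hr_stack.data,
                                            cfg.pretrain_patch, rng, upscale)
                xs.append(v)
                ys.append(s)
            x = np.stack(xs)
            y = np.stack(ys)
            pred = model.forward(x)
            loss, grad = recon_loss(pred, y, beta=cfg.gradient_loss_weight,
                                    with_grad=True)
            _check_finite(loss, step)
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            curve.append(loss)
            step += 1
        opt.decay_epoch()
    return model, curve


@dataclass
class FVCDModel:
    """Trained two-stage model plus its training history."""

    denoiser: FDenoise
    reconstructor: FRecon
    config: TrainingConfig
    history: dict = field(default_factory=dict)

    def save(self, path: str | Path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, p in enumerate(self.denoiser.params()):
            arrays[f"d{i}"] = p.value
        for i, p in enumerate(self.reconstructor.params()):
            arrays[f"r{i}"] = p.value
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {"denoise_spec": self.denoiser.spec.to_dict(),
                "recon_spec": self.reconstructor.spec.to_dict(),
                "training": {k: (list(v) if isinstance(v, tuple) else v)
                             for k, v in self.config.__dict__.items()}}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "FVCDModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        dspec = DenoiseNetSpec(**meta["denoise_spec"])
        rmeta = dict(meta["recon_spec"])
        rmeta["dilation_rates"] = tuple(rmeta["dilation_rates"])
        rmeta["dilation_widths"] = tuple(rmeta["dilation_widths"])
        rspec = ReconNetSpec(**rmeta)
        tmeta = dict(meta["training"])
        for k in ("pretrain_patch", "joint_patch"):
            tmeta[k] = tuple(tmeta[k])
        cfg = TrainingConfig(**tmeta)
        model = cls(FDenoise(dspec, seed=cfg.seed),
                    FRecon(rspec, seed=cfg.seed), cfg)
        data = np.load(path.with_suffix(".npz"))
        model.denoiser.set_state(
            [data[f"d{i}"] for i in range(len(model.denoiser.params()))])
        model.reconstructor.set_state(
            [data[f"r{i}"] for i in range(len(model.reconstructor.params()))])
        return model


def train_joint(dataset, denoiser: FDenoise, reconstructor: FRecon,
                cfg: TrainingConfig) -> FVCDModel:
    """Joint optimization of both sub-nets under the 0.2/0.8 weighted loss.

    The dataset is split into train/validation; after every epoch the
    joint loss on the validation triplets (full views, no patching) is
    evaluated and the parameters of the best epoch are restored at the
    end.
    """
    n_val = max(1, int(round(cfg.validation_fraction * len(dataset))))
    if n_val >= len(dataset):
        raise ValueError("dataset too small for a validation split")
    rng = np.random.default_rng(cfg.seed + 303)
    order = rng.permutation(len(dataset))
    val_set = [dataset[i] for i in order[:n_val]]
    train_set = [dataset[i] for i in order[n_val:]]

    params = denoiser.params() + reconstructor.params()
    opt = Adam(params, lr=cfg.learning_rate, lr_decay=cfg.lr_decay)
    upscale = reconstructor.spec.upscale
    train_curve, val_curve, val_metric_curve = [], [], []
    best = None
    step = 0
    for _ in range(cfg.epochs):
        for batch in _batches(len(train_set), cfg.batch_size, rng):
            xs, cs, ss = [], [], []
            for i in batch:
                t = train_set[i]
                ph = min(cfg.joint_patch[0], t.noisy_views.data.shape[1])
                pw = min(cfg.joint_patch[1], t.noisy_views.data.shape[2])
                ph -= ph % 2
                pw -= pw % 2
                r0 = int(rng.integers(0, t.noisy_views.data.shape[1] - ph + 1))
                c0 = int(rng.integers(0, t.noisy_views.data.shape[2] - pw + 1))
                xs.append(t.noisy_views.data[:, r0:r0 + ph, c0:c0 + pw])
                cs.append(t.clean_views.data[:, r0:r0 + ph, c0:c0 + pw])
                ss.append(t.hr_stack.data[:, r0 * upscale:(r0 + ph) * upscale,
                                          c0 * upscale:(c0 + pw) * upscale])
            x, c, s = np.stack(xs), np.stack(cs), np.stack(ss)
            den = denoiser.forward(x)
            vol = reconstructor.forward(den)
            dl, dgrad = denoise_loss(den, c, alpha=cfg.l1_fraction,
                                     with_grad=True)
            rl, rgrad = recon_loss(vol, s, beta=cfg.gradient_loss_weight,
                                   with_grad=True)
            loss = joint_loss(dl, rl, cfg)
            _check_finite(loss, step)
            opt.zero_grad()
            g_den_from_recon = reconstructor.backward(
                cfg.recon_loss_weight * rgrad)
            denoiser.backward(cfg.denoise_loss_weight * dgrad
                              + g_den_from_recon)
            opt.step()
            train_curve.append(loss)
            step += 1
        opt.decay_epoch()
        vl, vssim = _validate(val_set, denoiser, reconstructor, cfg, upscale)
        val_curve.append(vl)
        val_metric_curve.append(vssim if cfg.checkpoint_metric == "ssim"
                                else -vl)
        if best is None or val_metric_curve[-1] > best[0]:
            best = (val_metric_curve[-1], denoiser.get_state(),
                    reconstructor.get_state())
    denoiser.set_state(best[1])
    reconstructor.set_state(best[2])
    history = {"train_loss": train_curve, "val_loss": val_curve,
               "val_metric": val_metric_curve,
               "best_epoch": select_best_epoch(val_metric_curve, mode="max")}
    return FVCDModel(denoiser, reconstructor, cfg, history)


def _validate(val_set, denoiser, reconstructor, cfg, upscale):
    """Mean validation joint loss and mean validation volume SSIM."""
    from .metrics import ssim as _ssim
    total = 0.0
    ssims = []
    for t in val_set:
        x = t.noisy_views.data[None]
        den = denoiser.forward(x, train=False)
        vol = reconstructor.forward(den, train=False)
        dl = denoise_loss(den, t.clean_views.data[None],
                          alpha=cfg.l1_fraction)
        rl = recon_loss(vol, t.hr_stack.data[None],
                        beta=cfg.gradient_loss_weight)
        total += joint_loss(dl, rl, cfg)
        ssims.append(_ssim(t.hr_stack.data, np.maximum(vol[0], 0.0)))
    return total / len(val_set), float(np.mean(ssims))


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def infer(lf_or_views, model: FVCDModel,
          calibration: CalibrationResult | None = None,
          tile: int | None = None, overlap: int = 16):
    """Run the trained F-VCD on a light field or a view stack.

    Returns ``(denoised ViewStack, reconstructed Volume)``; the volume is
    clamped at zero (the networks are linear at the output so weak
    signals are never truncated during optimization).

    With ``tile`` set, the views are processed in margin-discard tiles:
    each core region of ``tile`` pixels is inferred with ``overlap``
    pixels of real image context on every side and only the core is
    kept.  Both must be multiples of 4 (the reconstructor's total
    downsampling) so every tile shares the whole image's stride phase;
    for purely convolutional sub-nets the result is then identical to
    whole-image inference wherever the margin covers the receptive
    field.  Global-pooling attention gates and instance normalization
    see per-tile statistics, which makes tiling approximate for such
    models.
    """
    if isinstance(lf_or_views, LFImage):
        if calibration is None:
            raise ValueError("calibration required for raw light-field input")
        views = extract_views(lf_or_views, calibration)
    else:
        views = lf_or_views
    x = views.data
    up = model.reconstructor.spec.upscale
    if tile is None:
        den = model.denoiser.forward(x[None], train=False)[0]
        vol = model.reconstructor.forward(den[None], train=False)[0]
    else:
        if tile % 4 or overlap % 4:
            raise ValueError("tile and overlap must be multiples of 4")
        h, w = x.shape[1:]
        if h % 4 or w % 4:
            raise ValueError("input height/width must be divisible by 4")
        psize = tile + 2 * overlap
        if psize > h or psize > w:
            raise ValueError("tile plus margins larger than the input")
        den = np.zeros_like(x)
        vol = np.zeros((model.reconstructor.spec.n_depths, h * up, w * up))
        for r0 in range(0, h, tile):
            for c0 in range(0, w, tile):
                rs = max(0, min(r0 - overlap, h - psize))
                cs = max(0, min(c0 - overlap, w - psize))
                patch = x[:, rs:rs + psize, cs:cs + psize]
                dp = model.denoiser.forward(patch[None], train=False)[0]
                vp = model.reconstructor.forward(dp[None], train=False)[0]
                r1, c1 = min(r0 + tile, h), min(c0 + tile, w)
                den[:, r0:r1, c0:c1] = dp[:, r0 - rs:r1 - rs, c0 - cs:c1 - cs]
                vol[:, r0 * up:r1 * up, c0 * up:c1 * up] = \
                    vp[:, (r0 - rs) * up:(r1 - rs) * up,
                       (c0 - cs) * up:(c1 - cs) * up]
    den = np.maximum(den, 0.0)
    vol = np.maximum(vol, 0.0)
    return (ViewStack(den, provenance="denoised"),
            Volume(vol, voxel_size_nm=(1.0, 1.0, 1.0)))
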