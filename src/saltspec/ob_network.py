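"""EfficientNet scaling/audit, OB stem allocation, training, Grad-CAM.

Two concerns live here.

**Architecture arithmetic.**  The EfficientNet family scales a fixed baseline
(B0: a 3x3/stride-2 stem of 32 filters, seven MBConv stages, a 1280-wide
head) by compound multipliers d = alpha^phi, w = beta^phi, r = gamma^phi with
alpha * beta^2 * gamma^2 ~ 2 and (alpha, beta, gamma) = (1.2, 1.1, 1.15).
:func:`make_network_spec` materialises any variant as an auditable parameter
manifest, and :func:`count_learnable_parameters` totals it per category
(convolution weights, dense weights, biases, batch-norm scale/offset).  Some
toolchains additionally report one per-channel batch-norm statistics vector
as "learnable"; ``include_bn_stat_sets`` reproduces that convention so a
published figure under either counting can be matched exactly.

**The OB input block.**  When the input is a stack of principal-component
score images, the channels carry known, very unequal shares of variance.
The OB ("optimized block") stem splits the input into single-channel planes
and gives channel i its own bank of 3x3x1 stem kernels, with bank sizes
apportioned to the channels' explained-variance contributions by largest
remainder (floor of one kernel per channel).  Banks are concatenated along
depth — total depth equals the ordinary stem width — followed by one shared
batch-norm and Swish, so everything downstream of the stem is identical to
the baseline.

A compact, fully self-contained CPU network (numpy forward/backward, Adam)
implements the OB stem and a reduced trunk so training, augmentation and
Grad-CAM are runnable end to end at desk scale; parameter-law audits always
use the true full-architecture manifest, never the reduced trunk.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import AllocationError, SaltSpecError, SplitError

# ---------------------------------------------------------------------------
# Compound scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalingSpec:
    """Compound-scaling constants and exponent."""

    alpha: float = 1.2
    beta: float = 1.1
    gamma: float = 1.15
    phi: float = 0.0

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 1:
            raise SaltSpecError("alpha, beta, gamma must all be >= 1")
        if self.phi < 0:
            raise SaltSpecError("phi must be >= 0")

    @property
    def depth_mult(self) -> float:
        return self.alpha ** self.phi

    @property
    def width_mult(self) -> float:
        return self.beta ** self.phi

    @property
    def resolution_mult(self) -> float:
        return self.gamma ** self.phi

    @property
    def constraint_value(self) -> float:
        return self.alpha * self.beta ** 2 * self.gamma ** 2


class CompoundMultipliers(NamedTuple):
    depth: float
    width: float
    resolution: float
    constraint: float


def compound_multipliers(spec: ScalingSpec) -> CompoundMultipliers:
    """(alpha^phi, beta^phi, gamma^phi) plus the constraint alpha*beta^2*gamma^2."""
    return CompoundMultipliers(
        spec.depth_mult, spec.width_mult, spec.resolution_mult, spec.constraint_value
    )


# ---------------------------------------------------------------------------
# Baseline architecture and variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageSpec:
    """One MBConv stage of the baseline."""

    expand: int
    kernel: int
    stride: int
    repeats: int
    out_channels: int


#: Published B0 stage configuration (taken as given; no architecture search).
B0_STAGES: tuple[StageSpec, ...] = (
    StageSpec(1, 3, 1, 1, 16),
    StageSpec(6, 3, 2, 2, 24),
    StageSpec(6, 5, 2, 2, 40),
    StageSpec(6, 3, 2, 3, 80),
    StageSpec(6, 5, 1, 3, 112),
    StageSpec(6, 5, 2, 4, 192),
    StageSpec(6, 3, 1, 1, 320),
)

B0_STEM_WIDTH = 32
B0_HEAD_WIDTH = 1280

#: (width_mult, depth_mult, input resolution) per variant; resolutions follow
#: the comparison table used downstream (B4 at 388).
VARIANTS: dict[str, tuple[float, float, int]] = {
    "B0": (1.0, 1.0, 224),
    "B2": (1.1, 1.2, 260),
    "B4": (1.4, 1.8, 388),
}


def round_filters(filters: int, width_mult: float, divisor: int = 8) -> int:
    """Width scaling with divisor-8 rounding (never below 90% of the target)."""
    scaled = filters * width_mult
    new = max(divisor, int(scaled + divisor / 2) // divisor * divisor)
    if new < 0.9 * scaled:
        new += divisor
    return int(new)


def round_repeats(repeats: int, depth_mult: float) -> int:
    return int(math.ceil(depth_mult * repeats))


# ---------------------------------------------------------------------------
# Stem-kernel allocation
# ---------------------------------------------------------------------------

@dataclass
class StemAllocation:
    """Per-input-channel stem kernel counts apportioned to variance shares."""

    kernel_counts: list[int]
    total: int
    contributions: list[float]

    def __post_init__(self) -> None:
        if sum(self.kernel_counts) != self.total:
            raise AllocationError("kernel counts must sum to the stem width")
        if any(c < 1 for c in self.kernel_counts):
            raise AllocationError("every channel must keep at least one kernel")
        for i in range(len(self.contributions)):
            for j in range(len(self.contributions)):
                if (self.contributions[i] > self.contributions[j]
                        and self.kernel_counts[i] < self.kernel_counts[j]):
                    raise AllocationError("allocation is not share-monotone")


def allocate_stem_kernels(contributions: Sequence[float], total: int) -> StemAllocation:
    """Largest-remainder apportionment of ``total`` kernels over variance shares.

    Shares are renormalized; each channel provisionally gets
    ``max(1, floor(total * share))``; remaining kernels go to channels by
    descending fractional remainder; any over-allocation caused by the
    one-kernel floor is resolved by decrementing the largest counts.  All
    ties break toward the lower channel index.
    """
    shares = np.asarray(contributions, dtype=float)
    n = len(shares)
    if n == 0:
        raise AllocationError("no channels to allocate to")
    if np.any(shares <= 0):
        raise AllocationError("contributions must all be positive")
    if total < n:
        raise AllocationError(f"total {total} < channel count {n}: infeasible")
    shares = shares / shares.sum()
    exact = total * shares
    counts = np.maximum(1, np.floor(exact).astype(int))
    # remainders relative to the provisional counts: channels bumped to the
    # one-kernel floor carry a negative remainder, keeping the allocation
    # monotone in the shares
    remainders = exact - counts
    surplus = total - counts.sum()
    if surplus > 0:
        order = sorted(range(n), key=lambda i: (-remainders[i], i))
        for i in order[:surplus]:
            counts[i] += 1
    while counts.sum() > total:
        candidates = [i for i in range(n) if counts[i] > 1]
        i = min(candidates, key=lambda i: (-counts[i], shares[i], i))
        counts[i] -= 1
    return StemAllocation(
        kernel_counts=counts.tolist(), total=total, contributions=list(map(float, shares))
    )


# ---------------------------------------------------------------------------
# Parameter manifest / audit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamEntry:
    name: str
    category: str           # conv_weight | dense_weight | bias | bn_scale_offset
    count: int
    bn_features: int = 0


@dataclass
class NetworkSpec:
    """Auditable description of a (possibly OB) EfficientNet variant."""

    variant: str
    input_resolution: int
    input_channels: int
    stem_width: int
    stages: tuple[StageSpec, ...]
    head_width: int
    n_classes: int
    ob_allocation: StemAllocation | None = None
    manifest: list[ParamEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ob_allocation is not None:
            if self.ob_allocation.total != self.stem_width:
                raise AllocationError(
                    f"allocation total {self.ob_allocation.total} != stem width {self.stem_width}"
                )
            if len(self.ob_allocation.kernel_counts) != self.input_channels:
                raise AllocationError("allocation length != input channel count")
        if not self.manifest:
            self.manifest = _build_manifest(self)

    @property
    def bn_feature_count(self) -> int:
        return sum(e.bn_features for e in self.manifest)


def _mbconv_entries(tag: str, cin: int, cout: int, expand: int, kernel: int) -> list[ParamEntry]:
    ec = expand * cin
    se = max(1, cin // 4)
    out: list[ParamEntry] = []
    if expand != 1:
        out += [
            ParamEntry(f"{tag}.expand.conv", "conv_weight", 1 * 1 * cin * ec),
            ParamEntry(f"{tag}.expand.bn", "bn_scale_offset", 2 * ec, bn_features=ec),
        ]
    out += [
        ParamEntry(f"{tag}.dwconv", "conv_weight", kernel * kernel * ec),
        ParamEntry(f"{tag}.dw.bn", "bn_scale_offset", 2 * ec, bn_features=ec),
        ParamEntry(f"{tag}.se.reduce", "conv_weight", ec * se),
        ParamEntry(f"{tag}.se.reduce.bias", "bias", se),
        ParamEntry(f"{tag}.se.expand", "conv_weight", se * ec),
        ParamEntry(f"{tag}.se.expand.bias", "bias", ec),
        ParamEntry(f"{tag}.project.conv", "conv_weight", ec * cout),
        ParamEntry(f"{tag}.project.bn", "bn_scale_offset", 2 * cout, bn_features=cout),
    ]
    return out


def _build_manifest(spec: NetworkSpec) -> list[ParamEntry]:
    entries: list[ParamEntry] = []
    if spec.ob_allocation is None:
        entries.append(
            ParamEntry("stem.conv", "conv_weight", 3 * 3 * spec.input_channels * spec.stem_width)
        )
    else:
        for i, k in enumerate(spec.ob_allocation.kernel_counts):
            entries.append(ParamEntry(f"stem.ob{i}.conv", "conv_weight", 3 * 3 * 1 * k))
    entries.append(
        ParamEntry("stem.bn", "bn_scale_offset", 2 * spec.stem_width,
                   bn_features=spec.stem_width)
    )
    cin = spec.stem_width
    for s_idx, stage in enumerate(spec.stages):
        for r in range(stage.repeats):
            tag = f"stage{s_idx + 1}.block{r + 1}"
            entries += _mbconv_entries(tag, cin, stage.out_channels, stage.expand, stage.kernel)
            cin = stage.out_channels
    entries += [
        ParamEntry("head.conv", "conv_weight", 1 * 1 * cin * spec.head_width),
        ParamEntry("head.bn", "bn_scale_offset", 2 * spec.head_width,
                   bn_features=spec.head_width),
        ParamEntry("classifier.weight", "dense_weight", spec.head_width * spec.n_classes),
        ParamEntry("classifier.bias", "bias", spec.n_classes),
    ]
    return entries


def make_network_spec(variant: str, input_channels: int, n_classes: int,
                      ob: bool = False,
                      allocation: StemAllocation | None = None) -> NetworkSpec:
    """Materialise a scaled (B0/B2/B4) variant as an auditable NetworkSpec."""
    if variant not in VARIANTS:
        raise SaltSpecError(f"unknown variant {variant!r}; choose from {sorted(VARIANTS)}")
    width_mult, depth_mult, resolution = VARIANTS[variant]
    stem_width = round_filters(B0_STEM_WIDTH, width_mult)
    stages = tuple(
        replace(
            s,
            out_channels=round_filters(s.out_channels, width_mult),
            repeats=round_repeats(s.repeats, depth_mult),
        )
        for s in B0_STAGES
    )
    head_width = round_filters(B0_HEAD_WIDTH, width_mult)
    if ob:
        if allocation is None:
            raise AllocationError("OB network requires a stem allocation")
    elif allocation is not None:
        raise AllocationError("allocation given but ob=False")
    return NetworkSpec(
        variant=variant,
        input_resolution=resolution,
        input_channels=input_channels,
        stem_width=stem_width,
        stages=stages,
        head_width=head_width,
        n_classes=n_classes,
        ob_allocation=allocation if ob else None,
    )


def parameter_breakdown(spec: NetworkSpec) -> dict[str, int]:
    """Per-category parameter totals for one NetworkSpec."""
    out = {"conv_weights": 0, "dense_weights": 0, "biases": 0, "bn_scale_offset": 0}
    key = {
        "conv_weight": "conv_weights",
        "dense_weight": "dense_weights",
        "bias": "biases",
        "bn_scale_offset": "bn_scale_offset",
    }
    for e in spec.manifest:
        out[key[e.category]] += e.count
    out["strict_total"] = sum(out.values())
    out["bn_feature_count"] = spec.bn_feature_count
    return out


def count_learnable_parameters(model, include_bn_stat_sets: int = 0) -> int:
    """Total learnable parameters of a NetworkSpec or a runnable model.

    ``include_bn_stat_sets`` adds that many per-channel batch-norm statistics
    vectors (0, 1 or 2), reproducing toolchains that report running statistics
    among the learnables.
    """
    if include_bn_stat_sets not in (0, 1, 2):
        raise SaltSpecError("include_bn_stat_sets must be 0, 1 or 2")
    if isinstance(model, NetworkSpec):
        strict = sum(e.count for e in model.manifest)
        return strict + include_bn_stat_sets * model.bn_feature_count
    params = model.parameters()
    strict = sum(int(np.asarray(p).size) for p in params)
    bn_features = getattr(model, "bn_feature_count", 0)
    return strict + include_bn_stat_sets * bn_features


# ---------------------------------------------------------------------------
# Compact runnable network (numpy, manual backprop)
# ---------------------------------------------------------------------------

class _Conv2d:
    """3x3-style convolution, stride s, zero padding, no bias."""

    def __init__(self, rng, c_in, c_out, kernel=3, stride=2, pad=1):
        fan_in = c_in * kernel * kernel
        self.w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel))
        self.stride, self.pad, self.kernel = stride, pad, kernel

    def forward(self, x):
        s, p, k = self.stride, self.pad, self.kernel
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        n, c, h, w = xp.shape
        ho, wo = (h - k) // s + 1, (w - k) // s + 1
        out = np.zeros((n, self.w.shape[0], ho, wo))
        for u in range(k):
            for v in range(k):
                patch = xp[:, :, u:u + (ho - 1) * s + 1:s, v:v + (wo - 1) * s + 1:s]
                out += np.einsum("nchw,oc->nohw", patch, self.w[:, :, u, v], optimize=True)
        self._xp_shape, self._xp = xp.shape, xp
        return out

    def backward(self, dout):
        s, p, k = self.stride, self.pad, self.kernel
        xp = self._xp
        n, c, h, w = xp.shape
        ho, wo = dout.shape[2], dout.shape[3]
        dw = np.zeros_like(self.w)
        dxp = np.zeros_like(xp)
        for u in range(k):
            for v in range(k):
                patch = xp[:, :, u:u + (ho - 1) * s + 1:s, v:v + (wo - 1) * s + 1:s]
                dw[:, :, u, v] = np.einsum("nohw,nchw->oc", dout, patch, optimize=True)
                dxp[:, :, u:u + (ho - 1) * s + 1:s, v:v + (wo - 1) * s + 1:s] += np.einsum(
                    "nohw,oc->nchw", dout, self.w[:, :, u, v], optimize=True
                )
        self.dw = dw
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class _BatchNorm2d:
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, dout, train):
        xhat, std = self._xhat, self._std
        self.dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta = dout.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        if not train:
            return dout * g / std[None, :, None, None]
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dxhat = dout * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) / std[None, :, None, None]
        return dx


def _swish(x):
    sig = 1.0 / (1.0 + np.exp(-x))
    return x * sig, sig


def _swish_grad(x, sig):
    return sig * (1.0 + x * (1.0 - sig))


class ObClassifierNet:
    """Compact OB/baseline classifier: stem -> BN -> Swish -> conv stages -> GAP -> FC.

    ``allocation`` switches the stem to per-channel 3x3x1 kernel banks whose
    sizes sum to ``stem_width``; with ``allocation=None`` the stem is one
    ordinary 3x3 convolution over all input channels.  Downstream layers are
    identical in both modes.
    """

    def __init__(self, input_channels: int, stem_width: int = 8,
                 stage_widths: Sequence[int] = (16,), n_classes: int = 2,
                 allocation: StemAllocation | None = None, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.input_channels = input_channels
        self.stem_width = stem_width
        self.allocation = allocation
        if allocation is not None:
            if allocation.total != stem_width:
                raise AllocationError("allocation total != stem width")
            if len(allocation.kernel_counts) != input_channels:
                raise AllocationError("allocation length != input channels")
            self.stem_convs = [
                _Conv2d(rng, 1, k, stride=2) for k in allocation.kernel_counts
            ]
        else:
            self.stem_convs = [_Conv2d(rng, input_channels, stem_width, stride=2)]
        self.stem_bn = _BatchNorm2d(stem_width)
        self.stage_convs, self.stage_bns = [], []
        c = stem_width
        for w in stage_widths:
            self.stage_convs.append(_Conv2d(rng, c, w, stride=2))
            self.stage_bns.append(_BatchNorm2d(w))
            c = w
        self.fc_w = rng.normal(0.0, math.sqrt(2.0 / c), size=(n_classes, c))
        self.fc_b = np.zeros(n_classes)
        self.n_classes = n_classes

    # -- parameter plumbing -------------------------------------------------
    def parameters(self):
        ps = [c.w for c in self.stem_convs] + [self.stem_bn.gamma, self.stem_bn.beta]
        for conv, bn in zip(self.stage_convs, self.stage_bns):
            ps += [conv.w, bn.gamma, bn.beta]
        ps += [self.fc_w, self.fc_b]
        return ps

    def gradients(self):
        gs = [c.dw for c in self.stem_convs] + [self.stem_bn.dgamma, self.stem_bn.dbeta]
        for conv, bn in zip(self.stage_convs, self.stage_bns):
            gs += [conv.dw, bn.dgamma, bn.dbeta]
        gs += [self.dfc_w, self.dfc_b]
        return gs

    @property
    def bn_feature_count(self) -> int:
        return self.stem_width + sum(bn.gamma.size for bn in self.stage_bns)

    def _buffers(self):
        bns = [self.stem_bn, *self.stage_bns]
        out = []
        for bn in bns:
            out += [bn.running_mean, bn.running_var]
        return out

    def state(self):
        """Learnable parameters plus batch-norm running statistics."""
        return [p.copy() for p in (*self.parameters(), *self._buffers())]

    def load_state(self, state):
        for p, s in zip((*self.parameters(), *self._buffers()), state):
            p[...] = s

    # -- forward / backward -------------------------------------------------
    def forward(self, x, train=False):
        x = np.asarray(x, dtype=np.float64)
        if self.allocation is not None:
            outs = [conv.forward(x[:, i:i + 1]) for i, conv in enumerate(self.stem_convs)]
            h = np.concatenate(outs, axis=1)
        else:
            h = self.stem_convs[0].forward(x)
        pre = self.stem_bn.forward(h, train)
        sig = 1.0 / (1.0 + np.exp(-pre))
        self._stem_swish = (pre, sig)
        h = pre * sig
        caches = []
        for conv, bn in zip(self.stage_convs, self.stage_bns):
            h = conv.forward(h)
            h = bn.forward(h, train)
            sig = 1.0 / (1.0 + np.exp(-h))
            caches.append((h, sig))
            h = h * sig
        self._stage_swish = caches
        self._feature_map = h                      # last conv feature map (post-act)
        self._pooled = h.mean(axis=(2, 3))
        logits = self._pooled @ self.fc_w.T + self.fc_b
        self._train_mode = train
        return logits

    def backward(self, dlogits):
        train = self._train_mode
        self.dfc_w = dlogits.T @ self._pooled
        self.dfc_b = dlogits.sum(axis=0)
        dpooled = dlogits @ self.fc_w
        n, c, hh, ww = self._feature_map.shape
        dh = np.broadcast_to(dpooled[:, :, None, None], (n, c, hh, ww)) / (hh * ww)
        self._dfeature_map = dh.copy()
        for conv, bn, (pre, sig) in zip(
            reversed(self.stage_convs), reversed(self.stage_bns), reversed(self._stage_swish)
        ):
            dh = dh * _swish_grad(pre, sig)
            dh = bn.backward(dh, train)
            dh = conv.backward(dh)
        pre, sig = self._stem_swish
        dh = dh * _swish_grad(pre, sig)
        dh = self.stem_bn.backward(dh, train)
        if self.allocation is not None:
            offset = 0
            dxs = []
            for i, conv in enumerate(self.stem_convs):
                k = self.allocation.kernel_counts[i]
                dxs.append(conv.backward(dh[:, offset:offset + k]))
                offset += k
            return np.concatenate(dxs, axis=1)
        return self.stem_convs[0].backward(dh)


class _Adam:
    def __init__(self, params, lr=0.01, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def build_network(variant: str, input_channels: int, n_classes: int,
                  ob: bool = False, allocation: StemAllocation | None = None,
                  profile: str = "full", seed: int = 0):
    """NetworkSpec plus (for the desk profile) a runnable model.

    ``profile='full'`` returns the audit-grade NetworkSpec with ``model=None``
    (the full MBConv trunk is specified, counted and scaled but not executed);
    ``profile='desk'`` additionally builds the compact runnable network with a
    stem of 8 kernels and one 16-wide stage, re-apportioning any OB allocation
    to the desk stem width.
    """
    spec = make_network_spec(variant, input_channels, n_classes, ob=ob, allocation=allocation)
    model = None
    if profile == "desk":
        desk_alloc = None
        if ob:
            desk_alloc = allocate_stem_kernels(allocation.contributions, total=max(8, input_channels))
        model = ObClassifierNet(
            input_channels=input_channels,
            stem_width=desk_alloc.total if desk_alloc else 8,
            stage_widths=(16,),
            n_classes=n_classes,
            allocation=desk_alloc,
            seed=seed,
        )
    elif profile != "full":
        raise SaltSpecError(f"unknown profile {profile!r}")
    return spec, model


# ---------------------------------------------------------------------------
# Training configuration and augmentation
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training hyperparameters and augmentation switches."""

    batch_size: int = 64
    learning_rate: float = 0.01
    optimizer: str = "adam"
    max_epochs: int = 30
    seed: int = 0
    flip_x: bool = True
    flip_y: bool = True
    scale_range: tuple[float, float] = (0.75, 1.25)
    shift_within_frame: bool = True
    augment: bool = True
    early_stop_acc: float | None = None

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise SaltSpecError("batch_size must be >= 1")
        lo, hi = self.scale_range
        if not (0 < lo <= hi < 2):
            raise SaltSpecError("scale_range must lie within (0, 2)")
        if self.optimizer != "adam":
            raise SaltSpecError("only the Adam optimizer is supported")


def _mask_bbox(mask: np.ndarray):
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if len(rows) == 0:
        return None
    return rows[0], rows[-1], cols[0], cols[-1]


def augment(images: np.ndarray, config: TrainConfig, seed: int,
            max_retries: int = 10) -> np.ndarray:
    """Seeded augmentation: flips, isotropic scale, in-frame translation.

    The identical geometric transform is applied to every channel.  The
    translation keeps the (scaled) mask bounding box inside the frame; if a
    drawn scale pushes the plant outside the frame the scale is re-drawn a
    bounded number of times before falling back to no rescale.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim != 3:
        raise SaltSpecError("augment expects a (C, H, W) stack")
    rng = np.random.default_rng(seed)
    out = images
    if config.flip_x and rng.random() < 0.5:
        out = out[:, :, ::-1]
    if config.flip_y and rng.random() < 0.5:
        out = out[:, ::-1, :]
    h, w = out.shape[1:]
    # the plant support drives the in-frame constraint; flips above apply to it too
    mask = np.abs(out).sum(axis=0) > 0
    lo, hi = config.scale_range
    scale = 1.0 if (lo, hi) == (1.0, 1.0) else float(rng.uniform(lo, hi))
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    bbox = _mask_bbox(mask)
    for _ in range(max_retries):
        if bbox is None or scale <= 1.0:
            break
        half_h = (bbox[1] - bbox[0] + 1) * scale / 2.0
        half_w = (bbox[3] - bbox[2] + 1) * scale / 2.0
        if half_h * 2 <= h and half_w * 2 <= w:
            break
        scale = float(rng.uniform(lo, hi))
    else:
        scale = min(scale, 1.0)
    shift_r = shift_c = 0.0
    if config.shift_within_frame and bbox is not None:
        r0, r1, c0, c1 = bbox
        # bbox corners after scaling about the frame center
        sr0, sr1 = [cy + (r - cy) * scale for r in (r0, r1)]
        sc0, sc1 = [cx + (c - cx) * scale for c in (c0, c1)]
        lo_r, hi_r = -sr0, (h - 1) - sr1
        lo_c, hi_c = -sc0, (w - 1) - sc1
        if hi_r > lo_r:
            shift_r = float(rng.uniform(lo_r, hi_r))
        if hi_c > lo_c:
            shift_c = float(rng.uniform(lo_c, hi_c))
    if scale == 1.0 and shift_r == 0.0 and shift_c == 0.0:
        return out.copy()
    # output pixel o maps to input pixel  (o - center - shift)/scale + center
    matrix = np.array([[1.0 / scale, 0.0], [0.0, 1.0 / scale]])
    offset = np.array([
        cy - (cy + shift_r) / scale,
        cx - (cx + shift_c) / scale,
    ])
    transformed = np.stack([
        ndi.affine_transform(ch, matrix, offset=offset, order=1, mode="constant", cval=0.0)
        for ch in out
    ])
    return transformed


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _xent_loss_grad(logits, y):
    p = _softmax(logits)
    n = len(y)
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


@dataclass
class TrainedClassifier:
    model: ObClassifierNet
    curves: pd.DataFrame
    best_epoch: int
    best_val_accuracy: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.forward(X, train=False).argmax(axis=1)


def _evaluate(model, X, y, batch=128):
    losses, correct = [], 0
    for i in range(0, len(X), batch):
        logits = model.forward(X[i:i + batch], train=False)
        loss, _ = _xent_loss_grad(logits, y[i:i + batch])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[i:i + batch]).sum())
    return float(np.sum(losses) / len(X)), correct / len(X)


def train_classifier(train_data, val_data, net: ObClassifierNet,
                     config: TrainConfig) -> TrainedClassifier:
    """Cross-entropy training with Adam, seeded, best-validation checkpointing.

    ``train_data`` / ``val_data`` are (X, y, pots) triples with X of shape
    (N, C, H, W), integer labels y (1 = salt-stressed) and per-sample pot IDs.
    Pot overlap between the splits is refused outright.
    """
    Xtr, ytr, pots_tr = train_data
    Xva, yva, pots_va = val_data
    leaked = set(pots_tr) & set(pots_va)
    if leaked:
        raise SplitError(f"pot leakage between train and validation: {sorted(leaked)[:5]}")
    Xtr = np.asarray(Xtr, dtype=np.float64)
    Xva = np.asarray(Xva, dtype=np.float64)
    ytr = np.asarray(ytr, dtype=int)
    yva = np.asarray(yva, dtype=int)
    rng = np.random.default_rng(config.seed)
    opt = _Adam(net.parameters(), lr=config.learning_rate)
    rows = []
    best_state, best_acc, best_epoch = net.state(), -1.0, -1
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(Xtr))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            if config.augment:
                xb = np.stack([
                    augment(Xtr[i], config, seed=int(rng.integers(2 ** 31)))
                    for i in idx
                ])
            else:
                xb = Xtr[idx]
            logits = net.forward(xb, train=True)
            loss, dlogits = _xent_loss_grad(logits, ytr[idx])
            net.backward(dlogits)
            opt.step(net.parameters(), net.gradients())
            epoch_losses.append(loss)
        tr_loss, tr_acc = _evaluate(net, Xtr, ytr)
        va_loss, va_acc = _evaluate(net, Xva, yva)
        rows.append({
            "epoch": epoch, "train_loss": tr_loss, "train_accuracy": tr_acc,
            "val_loss": va_loss, "val_accuracy": va_acc,
        })
        if va_acc > best_acc:
            best_acc, best_epoch, best_state = va_acc, epoch, net.state()
        if config.early_stop_acc is not None and va_acc >= config.early_stop_acc:
            break
    if best_epoch >= 0:
        net.load_state(best_state)
    curves = pd.DataFrame(rows, columns=[
        "epoch", "train_loss", "train_accuracy", "val_loss", "val_accuracy"
    ])
    return TrainedClassifier(
        model=net, curves=curves, best_epoch=best_epoch, best_val_accuracy=max(best_acc, 0.0)
    )


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

def grad_cam_map(model: ObClassifierNet, sample: np.ndarray, target_class: int) -> np.ndarray:
    """Grad-CAM saliency for one sample at the last convolutional feature map.

    Channel weights are the spatial means of d(score)/d(activation); the map
    is the rectified weighted sum of activations, bilinearly upsampled to the
    input resolution and normalized to [0, 1] by its maximum.
    """
    sample = np.asarray(sample, dtype=np.float64)
    if sample.ndim != 3:
        raise SaltSpecError("grad_cam_map expects one (C, H, W) sample")
    if not 0 <= target_class < model.n_classes:
        raise SaltSpecError(f"class index {target_class} out of range")
    x = sample[None]
    logits = model.forward(x, train=False)
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    model.backward(dlogits)
    activations = model._feature_map[0]
    grads = model._dfeature_map[0]
    weights = grads.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * activations).sum(axis=0), 0.0)
    h, w = sample.shape[1:]
    cam = ndi.zoom(cam, (h / cam.shape[0], w / cam.shape[1]), order=1)
    cam = cam[:h, :w]
    if cam.shape != (h, w):
        cam = np.pad(cam, ((0, h - cam.shape[0]), (0, w - cam.shape[1])), mode="edge")
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return cam
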