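"""Architectural building blocks of the multi-scale attention segmentation
network and the three task-specific risk branches, as pure NumPy operators.

The blocks implement, at any scale:

* the multi-scale cross-spatial attention gate
  ``Y = sigmoid(sum_s W_s . F_s(X)) * X`` with channels allocated 50% to the
  primary scale and 25% each to the intermediate and largest receptive field;
* the distance-aware boundary gate ``G = a tanh(b SDF) + c``;
* deformable convolution ``y(p) = sum_n w(p_n) x(p + p_n + dp_n)`` with
  trilinear sampling and zero padding;
* a five-level encoder with channel schedule {C0, 2C0, 4C0, 8C0, 16C0};
* the ASPP / deformable / Gabor-LBP task branches with FC heads
  ([512, 256, 128, 1] at full scale, scalable down for toy training).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import local_binary_pattern
from skimage.filters import gabor_kernel

from .volumes import ADHESION, LabelVolume, PLEURA, TUMOR, VESSEL

#: Canonical ASPP dilation rate set (four parallel branches).
ASPP_RATES = (1, 6, 12, 18)
#: FC head widths at full (paper) scale.
FC_HEAD_WIDTHS = (512, 256, 128, 1)
#: Gabor bank: 8 orientations x 3 scales.
GABOR_ORIENTATIONS = 8
GABOR_SCALES = 3

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


# ---------------------------------------------------------------------------
# EMSA-CSL attention block


@dataclass
class AttentionBlockParams:
    """Multi-scale attention block configuration.

    ``fractions`` allocate the input channels to the scale branches (primary,
    intermediate, largest); ``dilations`` set each branch's receptive field;
    ``weights`` are the learnable per-channel weights (zeros by default, which
    makes the block an exact 0.5*identity — a useful reduction check).
    """

    channels: int
    fractions: tuple[float, ...] = (0.5, 0.25, 0.25)
    dilations: tuple[int, ...] = (1, 2, 3)
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("channel fractions must sum to 1")
        if len(self.fractions) != len(self.dilations):
            raise ValueError("one dilation per scale branch is required")
        if self.weights is None:
            self.weights = np.zeros(self.channels)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.channels,):
            raise ValueError("weights must be per-channel, shape (C,)")

    def channel_split(self) -> list[int]:
        """e.g. C=32 with (0.5, 0.25, 0.25) -> [16, 8, 8]."""
        split = [int(round(f * self.channels)) for f in self.fractions[:-1]]
        split.append(self.channels - sum(split))
        return split


def _dilated_box_kernel(dilation: int) -> np.ndarray:
    size = 2 * dilation + 1
    k = np.zeros((size,) * 3)
    k[::dilation, ::dilation, ::dilation] = 1.0 / 27.0
    return k


def _dilated_box_filter(x: np.ndarray, dilation: int) -> np.ndarray:
    """Atrous 3x3x3 mean filter (edge-replicated), computed as 27 shifted
    samples — equivalent to correlating with ``_dilated_box_kernel`` but
    independent of the dilation rate in cost."""
    r = dilation
    xp = np.pad(x, r, mode="edge")
    out = np.zeros_like(x, dtype=float)
    n0, n1, n2 = x.shape
    for di in (-r, 0, r):
        for dj in (-r, 0, r):
            for dk in (-r, 0, r):
                out += xp[
                    r + di : r + di + n0, r + dj : r + dj + n1, r + dk : r + dk + n2
                ]
    return out / 27.0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def emsa_csl_block(x: np.ndarray, params: AttentionBlockParams) -> np.ndarray:
    """Y = sigmoid(sum_s W_s . F_s(X)) * X, channels split across scales.

    ``x`` has shape (C, D, H, W); each scale branch filters its channel
    allocation with a dilated 3x3x3 smoothing convolution F_s.
    """
    if x.ndim != 4 or x.shape[0] != params.channels:
        raise ValueError(
            f"expected input of shape ({params.channels}, D, H, W), got {x.shape}"
        )
    filtered = np.empty_like(x, dtype=float)
    start = 0
    for n_ch, dil in zip(params.channel_split(), params.dilations):
        for c in range(start, start + n_ch):
            filtered[c] = _dilated_box_filter(x[c].astype(float), dil)
        start += n_ch
    gate = _sigmoid(params.weights[:, None, None, None] * filtered)
    return gate * x


# ---------------------------------------------------------------------------
# Distance-aware gating


def distance_gate(
    features: np.ndarray, sdf: np.ndarray, alpha: float, beta: float, gamma: float
) -> np.ndarray:
    """Gated features = (alpha * tanh(beta * SDF) + gamma) * features.

    ``features`` may be (D, H, W) or (C, D, H, W) co-registered with ``sdf``.
    """
    if features.shape[-3:] != sdf.shape:
        raise ValueError(f"feature shape {features.shape} does not match SDF {sdf.shape}")
    gate = alpha * np.tanh(beta * sdf) + gamma
    return gate * features


# ---------------------------------------------------------------------------
# Deformable convolution


def deformable_conv(
    x: np.ndarray, kernel: np.ndarray, offsets: np.ndarray | None = None
) -> np.ndarray:
    """y(p) = sum_n w(p_n) x(p + p_n + dp_n), trilinear at fractional positions.

    ``offsets`` has shape (n_taps, 3): one learned offset per kernel tap
    (shared across positions). Out-of-bounds samples are zero-padded. With all
    offsets zero, the operator equals a standard (correlation) convolution.
    """
    if x.ndim != 3:
        raise ValueError("expected a 3D input")
    taps = np.argwhere(np.ones(kernel.shape, dtype=bool)) - np.asarray(kernel.shape) // 2
    if offsets is None:
        offsets = np.zeros((len(taps), 3))
    offsets = np.asarray(offsets, dtype=float)
    if offsets.shape != (len(taps), 3):
        raise ValueError(f"offsets must have shape ({len(taps)}, 3)")
    grid = np.meshgrid(*[np.arange(n, dtype=float) for n in x.shape], indexing="ij")
    out = np.zeros(x.shape, dtype=float)
    weights = kernel.ravel()
    for n, (tap, w) in enumerate(zip(taps, weights)):
        if w == 0 and np.all(offsets[n] == 0):
            continue
        coords = [g + tap[i] + offsets[n, i] for i, g in enumerate(grid)]
        out += w * ndimage.map_coordinates(x.astype(float), coords, order=1, mode="constant", cval=0.0)
    return out


# ---------------------------------------------------------------------------
# Encoder


@dataclass
class Encoder3D:
    """Five-level random-feature encoder with the {C0..16C0} channel schedule.

    Weights are fixed at construction from ``seed`` (random-projection
    features): each level mixes channels with a 1x1x1 projection, smooths with
    a 3x3x3 box filter, applies ReLU and downsamples by 2.
    """

    c0: int = 8
    n_levels: int = 5
    in_channels: int = 1
    seed: int = 0
    projections: list[np.ndarray] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        self.projections = []
        c_in = self.in_channels
        for c_out in self.channels:
            self.projections.append(rng.normal(0, 1.0 / np.sqrt(c_in), size=(c_out, c_in)))
            c_in = c_out

    @property
    def channels(self) -> list[int]:
        return [self.c0 * 2**i for i in range(self.n_levels)]

    def forward(self, x: np.ndarray) -> list[np.ndarray]:
        """x: (C_in, D, H, W) or (D, H, W) -> per-level feature maps."""
        if x.ndim == 3:
            x = x[None]
        feats = []
        cur = x.astype(float)
        for level, proj in enumerate(self.projections):
            mixed = np.tensordot(proj, cur, axes=(1, 0))
            smoothed = np.stack([ndimage.uniform_filter(m, size=3, mode="nearest") for m in mixed])
            cur = np.maximum(smoothed, 0.0)
            feats.append(cur)
            cur = cur[:, ::2, ::2, ::2]
        return feats


# ---------------------------------------------------------------------------
# Task branches


def fc_head_widths(scale: float = 1.0) -> tuple[int, ...]:
    """FC head widths, [512, 256, 128, 1] at scale 1, proportionally smaller
    for toy models (the final single-logit layer is fixed)."""
    return tuple(max(int(round(w * scale)), 1) for w in FC_HEAD_WIDTHS[:-1]) + (1,)


def _one_hot_channels(vol: LabelVolume) -> dict[str, np.ndarray]:
    return {
        "tumor": (vol.labels == TUMOR).astype(float),
        "pleura": (vol.labels == PLEURA).astype(float),
        "vessel": (vol.labels == VESSEL).astype(float),
        "adhesion": (vol.labels == ADHESION).astype(float),
    }


def aspp_features(vol: LabelVolume, rates: tuple[int, ...] = ASPP_RATES) -> np.ndarray:
    """Pneumothorax-branch features: parallel atrous 3x3x3 context filters on
    the pleural channel pooled over the tumor (plus global average pooling and
    the tumor volume fraction)."""
    ch = _one_hot_channels(vol)
    tumor = ch["tumor"] > 0
    if not tumor.any():
        raise ValueError("tumor label is required")
    feats = []
    for r in rates:
        resp = _dilated_box_filter(ch["pleura"], r)
        feats.append(float(resp[tumor].mean()))
    feats.append(float(ch["pleura"].mean()))  # global average pooling context
    feats.append(float(tumor.mean()))
    return np.asarray(feats)


def deformable_branch_features(vol: LabelVolume, seed: int = 0) -> np.ndarray:
    """Hemorrhage-branch features: a deformable-convolution stack over the
    vessel channel, pooled over progressively dilated tumor neighborhoods."""
    ch = _one_hot_channels(vol)
    tumor = ch["tumor"] > 0
    if not tumor.any():
        raise ValueError("tumor label is required")
    rng = np.random.default_rng(seed)
    kernel = np.full((3, 3, 3), 1.0 / 27.0)
    offsets = rng.normal(0, 0.5, size=(27, 3))
    resp = deformable_conv(ch["vessel"], kernel, offsets)
    resp = ndimage.uniform_filter(resp, size=5, mode="nearest")
    feats = []
    region = tumor
    for it in (1, 3, 6):
        region = ndimage.binary_dilation(tumor, structure=_STRUCT6, iterations=it)
        feats.append(float(resp[region].mean()))
        feats.append(float(resp[region].max()))
    return np.asarray(feats)


def _gabor_bank():
    freqs = (0.1, 0.2, 0.3)
    thetas = [np.pi * i / GABOR_ORIENTATIONS for i in range(GABOR_ORIENTATIONS)]
    return [(f, t, gabor_kernel(frequency=f, theta=t)) for f in freqs for t in thetas]


_GABOR_BANK = None


def gabor_lbp_features(vol: LabelVolume) -> np.ndarray:
    """Pleural-reaction-branch features: Gabor energies (8 orientations x 3
    scales, slice-wise on the axial plane through the tumor centroid) with
    attention-weighted aggregation per scale, plus a uniform-LBP histogram."""
    global _GABOR_BANK
    ch = _one_hot_channels(vol)
    tumor = ch["tumor"] > 0
    if not tumor.any():
        raise ValueError("tumor label is required")
    z = int(round(np.argwhere(tumor)[:, 2].mean()))
    img = ch["adhesion"][:, :, z] + 0.5 * ch["pleura"][:, :, z] + 0.25 * ch["tumor"][:, :, z]

    if _GABOR_BANK is None:
        _GABOR_BANK = _gabor_bank()
    energies = np.empty(len(_GABOR_BANK))
    for i, (_f, _t, k) in enumerate(_GABOR_BANK):
        resp = ndimage.convolve(img, np.real(k), mode="nearest")
        energies[i] = float(np.sqrt((resp**2).mean()))
    # attention-weighted aggregation across orientations, per scale
    feats = []
    for s in range(GABOR_SCALES):
        e = energies[s * GABOR_ORIENTATIONS : (s + 1) * GABOR_ORIENTATIONS]
        w = np.exp(e - e.max())
        w = w / w.sum()
        feats.append(float((w * e).sum()))
    # the composed label image is 1/4-step quantized; integer codes avoid
    # LBP's sensitivity to float rounding
    codes = local_binary_pattern(np.rint(img * 4).astype(np.int32), P=8, R=1, method="uniform")
    hist, _ = np.histogram(codes, bins=np.arange(11) - 0.5, density=True)
    feats.extend(hist.tolist())
    feats.append(float(ch["adhesion"].sum() * np.prod(vol.spacing[:2])))
    return np.asarray(feats)


BRANCH_FEATURIZERS = {
    "pneumothorax": aspp_features,
    "hemorrhage": deformable_branch_features,
    "pleural": gabor_lbp_features,
}


def branch_features(vol: LabelVolume, branch_kind: str) -> np.ndarray:
    if branch_kind not in BRANCH_FEATURIZERS:
        raise ValueError(
            f"unknown branch '{branch_kind}', expected one of {sorted(BRANCH_FEATURIZERS)}"
        )
    return BRANCH_FEATURIZERS[branch_kind](vol)


# ---------------------------------------------------------------------------
# FC head (trainable MLP)


class MLPHead:
    """Fully connected head ending in a single logit, with ReLU activations
    and dropout on hidden layers. Forward/backward are explicit NumPy."""

    def __init__(self, n_in: int, widths: tuple[int, ...] = (32, 16, 8, 1), dropout: float = 0.3, seed: int = 0):
        if widths[-1] != 1:
            raise ValueError("head must end in a single logit")
        rng = np.random.default_rng(seed)
        self.widths = tuple(widths)
        self.dropout = dropout
        self.W, self.b = [], []
        prev = n_in
        for w in widths:
            self.W.append(rng.normal(0, np.sqrt(2.0 / prev), size=(w, prev)))
            self.b.append(np.zeros(w))
            prev = w

    @property
    def parameters(self) -> list[np.ndarray]:
        return self.W + self.b

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None):
        """Returns (logit, cache). x: (n_in,)."""
        acts = [np.asarray(x, dtype=float)]
        masks = []
        h = acts[0]
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = W @ h + b
            if i < len(self.W) - 1:
                h = np.maximum(z, 0.0)
                if train and self.dropout > 0:
                    if rng is None:
                        raise ValueError("training forward requires an rng for dropout")
                    mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(np.ones_like(h))
            else:
                h = z
            acts.append(h)
        return float(h[0]), (acts, masks)

    def backward(self, cache, dlogit: float) -> list[np.ndarray]:
        """Gradient of a scalar loss wrt parameters, given d loss / d logit."""
        acts, masks = cache
        gW = [np.zeros_like(W) for W in self.W]
        gb = [np.zeros_like(b) for b in self.b]
        delta = np.array([dlogit])
        for i in range(len(self.W) - 1, -1, -1):
            h_in = acts[i]
            gW[i] = np.outer(delta, h_in)
            gb[i] = delta
            if i > 0:
                delta = self.W[i].T @ delta
                delta = delta * masks[i - 1] * (acts[i] > 0)
        return gW + gb
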