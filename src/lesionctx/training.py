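"""Toy multi-task training on phantom cohorts, yielding a frozen risk model.

The shared encoder is a fixed seeded random-feature stage (the task branches'
featurizers); training fits the three FC risk heads and a voxelwise logistic
segmentation layer with the composite loss, using a NumPy AdamW and the cosine
learning-rate schedule. The result satisfies the frozen-model predict contract
(``predict(label_volume) -> {risk: probability}``) so it is interchangeable
with the surrogate model in every audit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import losses as lo
from . import network as net
from .phantoms import CaseRecord, Cohort, RISK_NAMES
from .volumes import LabelVolume, TUMOR, Volume

MODEL_FORMAT_VERSION = "lesionctx-toy-1"

RISK_TO_BRANCH = {
    "pneumothorax": "pneumothorax",
    "hemorrhage": "hemorrhage",
    "pleural_reaction": "pleural",
}


@dataclass
class TrainConfig:
    """Toy-scale training configuration.

    Full-scale reference values: C0=32, FC head [512, 256, 128, 1], 200
    epochs; the toy defaults shrink the encoder and heads but keep the
    optimizer settings (AdamW, lr 1e-3, betas (0.9, 0.999), weight decay
    1e-4), batch size 2 with 4-step gradient accumulation, dropout 0.3 and the
    cosine schedule.
    """

    c0: int = 8
    head_widths: tuple[int, ...] = (32, 16, 8, 1)
    epochs: int = 30
    lr_max: float = 1e-3
    lr_min: float = 1e-5
    batch_size: int = 2
    accum_steps: int = 4
    dropout: float = 0.3
    weight_decay: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0
    train_segmentation: bool = True
    loss: lo.LossConfig = field(default_factory=lo.LossConfig)

    @classmethod
    def toy(cls, **overrides) -> "TrainConfig":
        """Preset for ~40-case toy runs: the reference learning rate (1e-3)
        with 4-step accumulation cannot converge inside a 30-epoch toy
        budget, so the preset raises lr_max to 5e-3 and updates per batch."""
        defaults = {"lr_max": 5e-3, "accum_steps": 1, "epochs": 30}
        defaults.update(overrides)
        return cls(**defaults)


class AdamW:
    """Decoupled-weight-decay Adam over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], beta1=0.9, beta2=0.999, weight_decay=1e-4, eps=1e-8):
        self.params = params
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.weight_decay, self.eps = beta1, beta2, weight_decay, eps
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p -= lr * (m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _seg_feature_maps(intensity: Volume) -> np.ndarray:
    x = intensity.data.astype(float)
    return np.stack(
        [
            x,
            ndimage.uniform_filter(x, size=3, mode="nearest"),
            ndimage.uniform_filter(x, size=7, mode="nearest"),
        ]
    )


class ToyRiskModel:
    """Frozen multi-task predictor over label volumes.

    Featurization (the shared random-feature encoder stage and the three
    branch feature extractors) is fixed by ``branch_seed``; the trained state
    is the per-branch feature standardization, the FC heads and the voxelwise
    segmentation weights.
    """

    def __init__(self, config: TrainConfig):
        self.config = config
        self.branch_seed = config.seed
        self.heads: dict[str, net.MLPHead] = {}
        self.feature_stats: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.seg_weights: np.ndarray | None = None  # (n_channels + 1,), last is bias
        self.history: list[dict[str, float]] = []
        self.version = MODEL_FORMAT_VERSION

    # -- featurization -----------------------------------------------------
    def features(self, vol: LabelVolume, risk: str) -> np.ndarray:
        branch = RISK_TO_BRANCH[risk]
        if branch == "hemorrhage":
            raw = net.deformable_branch_features(vol, seed=self.branch_seed)
        else:
            raw = net.branch_features(vol, branch)
        mu, sd = self.feature_stats.get(risk, (np.zeros_like(raw), np.ones_like(raw)))
        return (raw - mu) / sd

    # -- frozen predict contract -------------------------------------------
    def predict(self, vol: LabelVolume) -> dict[str, float]:
        out = {}
        for risk in RISK_NAMES:
            x = self.features(vol, risk)
            logit, _ = self.heads[risk].forward(x, train=False)
            out[risk] = float(_sigmoid(logit))
        return out

    def segment(self, intensity: Volume) -> np.ndarray:
        if self.seg_weights is None:
            raise RuntimeError("model was trained without the segmentation head")
        f = _seg_feature_maps(intensity)
        z = np.tensordot(self.seg_weights[:-1], f, axes=(0, 0)) + self.seg_weights[-1]
        return _sigmoid(z)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "branch_seed": self.branch_seed,
            "head_widths": list(self.config.head_widths),
            "dropout": self.config.dropout,
            "feature_stats": {
                r: {"mean": mu.tolist(), "sd": sd.tolist()}
                for r, (mu, sd) in self.feature_stats.items()
            },
            "heads": {
                r: {
                    "W": [w.tolist() for w in h.W],
                    "b": [b.tolist() for b in h.b],
                }
                for r, h in self.heads.items()
            },
            "seg_weights": None if self.seg_weights is None else self.seg_weights.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ToyRiskModel":
        if d.get("version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model version {d.get('version')!r}")
        cfg = TrainConfig(head_widths=tuple(d["head_widths"]), dropout=d["dropout"], seed=d["branch_seed"])
        model = cls(cfg)
        for r, st in d["feature_stats"].items():
            model.feature_stats[r] = (np.asarray(st["mean"]), np.asarray(st["sd"]))
        for r, hd in d["heads"].items():
            W = [np.asarray(w) for w in hd["W"]]
            head = net.MLPHead(W[0].shape[1], tuple(w.shape[0] for w in W), dropout=cfg.dropout, seed=0)
            head.W = W
            head.b = [np.asarray(b) for b in hd["b"]]
            model.heads[r] = head
        if d["seg_weights"] is not None:
            model.seg_weights = np.asarray(d["seg_weights"])
        return model

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "ToyRiskModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _seg_loss_and_grad(p, g, w, f, config: lo.LossConfig):
    """L_seg = 1 - Dice + mix * focal for a voxelwise-logistic mask, with the
    analytic gradient wrt the linear weights."""
    eps = lo.PROB_CLAMP
    pc = np.clip(p, eps, 1 - eps)
    sp, sg = float(p.sum()), float(g.sum())
    inter = float((p * g).sum())
    dice = 2 * inter / (sp + sg) if sp + sg > 0 else 1.0
    ddice_dp = (2 * g * (sp + sg) - 2 * inter) / (sp + sg) ** 2

    a, gam = config.focal_alpha, config.focal_gamma
    p_t = np.where(g > 0.5, pc, 1 - pc)
    focal = float(np.mean(-a * (1 - p_t) ** gam * np.log(p_t)))
    dfocal_dpt = -a * (-gam * (1 - p_t) ** (gam - 1) * np.log(p_t) + (1 - p_t) ** gam / p_t)
    dfocal_dp = np.where(g > 0.5, dfocal_dpt, -dfocal_dpt) / p.size

    dl_dp = -ddice_dp + config.seg_focal_mix * dfocal_dp
    dl_dz = dl_dp * p * (1 - p)
    grad_w = np.tensordot(f, dl_dz, axes=((1, 2, 3), (0, 1, 2)))
    grad_b = float(dl_dz.sum())
    loss = 1 - dice + config.seg_focal_mix * focal
    return loss, np.concatenate([grad_w, [grad_b]])


def train_toy(cohort: Cohort | list[CaseRecord], config: TrainConfig | None = None) -> ToyRiskModel:
    """Train the toy multi-task model on a phantom cohort's training split.

    Fits the three branch FC heads (class-weighted BCE) and, when intensity
    volumes are present, the voxelwise segmentation layer (Dice + focal),
    jointly minimizing the composite loss with AdamW under the cosine
    schedule, batch size 2 and 4-step gradient accumulation. Deterministic
    given ``config.seed``.
    """
    config = config or TrainConfig()
    cases = cohort.cases if isinstance(cohort, Cohort) else list(cohort)
    train_cases = [c for c in cases if c.split == "train"] or cases
    rng = np.random.default_rng(config.seed)

    model = ToyRiskModel(config)

    # fixed featurization, standardized on the training split
    raw_feats: dict[str, list[np.ndarray]] = {r: [] for r in RISK_NAMES}
    for case in train_cases:
        for r in RISK_NAMES:
            raw_feats[r].append(model.features(case.volume, r))
    feat_by_risk = {}
    for r in RISK_NAMES:
        X = np.stack(raw_feats[r])
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        model.feature_stats[r] = (mu, sd)
        feat_by_risk[r] = (X - mu) / sd
        model.heads[r] = net.MLPHead(
            X.shape[1],
            config.head_widths,
            dropout=config.dropout,
            seed=config.seed + 101 * RISK_NAMES.index(r),
        )

    do_seg = config.train_segmentation and all(c.intensity is not None for c in train_cases)
    seg_feats = None
    if do_seg:
        seg_feats = [_seg_feature_maps(c.intensity) for c in train_cases]
        model.seg_weights = np.zeros(seg_feats[0].shape[0] + 1)

    params: list[np.ndarray] = []
    for r in RISK_NAMES:
        params.extend(model.heads[r].parameters)
    if do_seg:
        params.append(model.seg_weights)
    opt = AdamW(params, config.beta1, config.beta2, config.weight_decay)

    n = len(train_cases)
    cfg_loss = config.loss
    for epoch in range(config.epochs):
        lr = lo.cosine_lr(epoch, config.lr_min, config.lr_max, config.epochs)
        order = rng.permutation(n)
        epoch_losses = []
        micro = max(config.batch_size, 1)
        step = micro * max(config.accum_steps, 1)
        for start in range(0, n, step):
            chunk = order[start : start + step]
            grads = [np.zeros_like(p) for p in params]
            for ci in chunk:
                case = train_cases[ci]
                case_grads = [np.zeros_like(p) for p in params]
                pred_probs, caches = {}, {}
                pi = 0
                for r in RISK_NAMES:
                    head = model.heads[r]
                    logit, cache = head.forward(feat_by_risk[r][ci], train=True, rng=rng)
                    p = float(_sigmoid(logit))
                    pred_probs[r] = p
                    caches[r] = cache
                    y = float(case.outcomes[r])
                    w = cfg_loss.class_weights[r]
                    dlogit = cfg_loss.lambda_cls * w * (p - y)
                    hg = head.backward(cache, dlogit)
                    n_par = len(head.parameters)
                    for k in range(n_par):
                        case_grads[pi + k] += hg[k]
                    pi += n_par
                pred_mask = true_mask = None
                if do_seg:
                    f = seg_feats[ci]
                    z = np.tensordot(model.seg_weights[:-1], f, axes=(0, 0)) + model.seg_weights[-1]
                    pred_mask = _sigmoid(z)
                    true_mask = (case.volume.labels == TUMOR).astype(float)
                    _, seg_grad = _seg_loss_and_grad(pred_mask, true_mask, model.seg_weights, f, cfg_loss)
                    case_grads[-1] += cfg_loss.lambda_seg * seg_grad
                # L2 term of L_reg (decoupled weight decay is applied by AdamW)
                for k, p_arr in enumerate(params):
                    case_grads[k] += cfg_loss.lambda_reg * cfg_loss.l2_coefficient * 2.0 * p_arr
                comp = lo.composite_loss(
                    pred_mask, true_mask, pred_probs, case.outcomes, cfg_loss, parameters=params
                )
                if not np.isfinite(comp["total"]):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, case {case.case_id}: {comp}"
                    )
                epoch_losses.append(comp)
                for k in range(len(params)):
                    grads[k] += case_grads[k] / len(chunk)
            opt.step(grads, lr)
        mean_total = float(np.mean([c["total"] for c in epoch_losses]))
        model.history.append(
            {
                "epoch": epoch,
                "lr": lr,
                "total": mean_total,
                "cls": float(np.mean([c["cls"] for c in epoch_losses])),
                "seg": float(np.mean([c["seg"] for c in epoch_losses])),
            }
        )
    return model
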