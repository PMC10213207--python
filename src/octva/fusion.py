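"""Multimodal fusion models for postoperative visual-acuity prediction.

Five model variants share one architecture and differ only in which
modalities they fuse:

- I: horizontal B-scan only
- II: vertical B-scan only
- III: horizontal + vertical B-scans
- IV: both B-scans + preoperative BCVA
- V: both B-scans + preoperative BCVA + the seven macular indices

Each B-scan passes through a shared convolutional backbone that flattens
it into a 512-dim feature vector; the encoding stage turns each image
feature into a 128-dim token and each scalar modality (preoperative VA,
1-dim; morphological indices, 7-dim) into a 32-dim token, then projects
every token to a common fused width so they can be concatenated with a
learnable prediction token into one sequence. A transformer encoder
(multi-headed self-attention + layer norm + feed-forward blocks with
residual connections) fuses the sequence; the prediction token's output,
through a linear head, is the predicted postoperative BCVA in logMAR.

Training minimizes the RMSE loss sqrt(mean((y_hat - y)^2)) with SGD:
initial learning rate 0.01, decayed by 0.1 every 40 epochs, for at most
100 epochs; the checkpoint with the best validation MAE is returned.

No positional encoding is used: modality identity is carried entirely by
the per-modality projection weights, so the token set is unordered and
predictions are invariant to modality-token permutation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .errors import ConfigurationError, TrainingError, ValidationError
from .io import BScanImage, CohortRecord, load_image
from .nn import ConvBackbone, Linear, Module, SGD, Tensor, TransformerEncoderLayer, concat

__all__ = [
    "ModelVariant",
    "VARIANTS",
    "TokenSequence",
    "TrainConfig",
    "TrainedModel",
    "msa",
    "extract_image_features",
    "encode_tokens",
    "transformer_fuse",
    "split_dataset",
    "train_model",
    "predict",
]


@dataclass(frozen=True)
class ModelVariant:
    id: str
    uses_himg: bool
    uses_vimg: bool
    uses_preop_va: bool
    uses_indices: bool

    @property
    def n_tokens(self) -> int:
        """Modality tokens plus the prediction token."""
        return (
            int(self.uses_himg)
            + int(self.uses_vimg)
            + int(self.uses_preop_va)
            + int(self.uses_indices)
            + 1
        )


VARIANTS: dict[str, ModelVariant] = {
    "I": ModelVariant("I", True, False, False, False),
    "II": ModelVariant("II", False, True, False, False),
    "III": ModelVariant("III", True, True, False, False),
    "IV": ModelVariant("IV", True, True, True, False),
    "V": ModelVariant("V", True, True, True, True),
}


@dataclass
class TokenSequence:
    """An encoded token sequence: one token per active modality + the
    prediction token (last), all projected to the common fused width."""

    tokens: Tensor  # (batch, n_tokens, d_model)
    modalities: tuple[str, ...]

    @property
    def length(self) -> int:
        return self.tokens.shape[1]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    The learning-rate schedule (0.01, x0.1 every 40 epochs, at most 100
    epochs), the SGD optimizer and the RMSE loss are the model's defining
    training procedure; batch size, momentum, transformer depth/width and
    the input image side are implementation knobs.
    """

    max_epochs: int = 100
    lr0: float = 0.01
    lr_decay: float = 0.1
    lr_step_epochs: int = 40
    # the RMSE loss has a scale-free gradient; heavy momentum sustains
    # oscillation at short epoch budgets, so the default is moderate
    momentum: float = 0.5
    batch_size: int = 32
    seed: int = 0
    image_size: int = 224
    d_model: int = 128
    n_layers: int = 2
    n_heads: int = 4
    ffn_width: int = 256
    patience: int | None = None  # epochs without val improvement before stopping

    def __post_init__(self):
        if self.max_epochs <= 0 or self.lr0 <= 0 or self.batch_size <= 0:
            raise ValidationError("epochs, learning rate and batch size must be positive")


IMAGE_TOKEN_DIM = 128
SCALAR_TOKEN_DIM = 32
N_INDICES = 7


def msa(Q: np.ndarray, K: np.ndarray, V: np.ndarray, d_k: float) -> np.ndarray:
    """Scaled dot-product attention: softmax(Q K^T / sqrt(d_k)) V.

    Plain-numpy reference form of the attention block; the trainable
    layers use the autodiff equivalent. Softmax is applied row-wise over
    the key axis.
    """
    Q, K, V = (np.asarray(m, dtype=float) for m in (Q, K, V))
    if Q.shape[-1] != K.shape[-1] or K.shape[-2] != V.shape[-2]:
        raise ValidationError("Q/K/V shapes are not conformable")
    if d_k <= 0:
        raise ValidationError("d_k must be positive")
    scores = Q @ np.swapaxes(K, -1, -2) / math.sqrt(d_k)
    scores -= scores.max(axis=-1, keepdims=True)
    w = np.exp(scores)
    w /= w.sum(axis=-1, keepdims=True)
    return w @ V


class VAFusionNet(Module):
    """The full fusion network for one model variant."""

    def __init__(self, variant: ModelVariant, cfg: TrainConfig, rng: np.random.Generator):
        self.variant = variant
        self.cfg = cfg
        d = cfg.d_model
        self.backbone = ConvBackbone(rng)  # shared between the two B-scans
        if variant.uses_himg:
            self.h_token = Linear(ConvBackbone.FEATURE_DIM, IMAGE_TOKEN_DIM, rng)
            self.h_proj = Linear(IMAGE_TOKEN_DIM, d, rng)
        if variant.uses_vimg:
            self.v_token = Linear(ConvBackbone.FEATURE_DIM, IMAGE_TOKEN_DIM, rng)
            self.v_proj = Linear(IMAGE_TOKEN_DIM, d, rng)
        if variant.uses_preop_va:
            self.va_token = Linear(1, SCALAR_TOKEN_DIM, rng)
            self.va_proj = Linear(SCALAR_TOKEN_DIM, d, rng)
        if variant.uses_indices:
            self.idx_token = Linear(N_INDICES, SCALAR_TOKEN_DIM, rng)
            self.idx_proj = Linear(SCALAR_TOKEN_DIM, d, rng)
        self.pred_token = Tensor(rng.normal(0.0, 0.02, size=(1, 1, d)), requires_grad=True)
        self.encoder = [
            TransformerEncoderLayer(d, cfg.n_heads, cfg.ffn_width, rng)
            for _ in range(cfg.n_layers)
        ]
        self.head = Linear(d, 1, rng, scale=0.01)

    # ---- encoding ------------------------------------------------------
    def encode_tokens(
        self,
        himg: Tensor | None,
        vimg: Tensor | None,
        preop_va: Tensor | None,
        indices: Tensor | None,
    ) -> TokenSequence:
        v = self.variant
        need = {
            "himg": (v.uses_himg, himg),
            "vimg": (v.uses_vimg, vimg),
            "preop_va": (v.uses_preop_va, preop_va),
            "indices": (v.uses_indices, indices),
        }
        for name, (used, val) in need.items():
            if used and val is None:
                raise ConfigurationError(
                    f"variant {v.id} requires modality {name!r} but it is missing"
                )
        toks: list[Tensor] = []
        mods: list[str] = []
        n = None
        if v.uses_himg:
            f = self.backbone(himg)
            toks.append(self.h_proj(self.h_token(f)))
            mods.append("himg")
            n = f.shape[0]
        if v.uses_vimg:
            f = self.backbone(vimg)
            toks.append(self.v_proj(self.v_token(f)))
            mods.append("vimg")
            n = f.shape[0]
        if v.uses_preop_va:
            toks.append(self.va_proj(self.va_token(preop_va)))
            mods.append("preop_va")
            n = preop_va.shape[0]
        if v.uses_indices:
            toks.append(self.idx_proj(self.idx_token(indices)))
            mods.append("indices")
            n = indices.shape[0]
        d = self.cfg.d_model
        seq = [t.reshape(n, 1, d) for t in toks]
        ones = Tensor(np.ones((n, 1, 1)))
        seq.append(ones @ self.pred_token.reshape(1, d))  # broadcast pred token
        return TokenSequence(tokens=concat(seq, axis=1), modalities=tuple(mods) + ("pred",))

    # ---- fusion --------------------------------------------------------
    def fuse(self, seq: TokenSequence) -> Tensor:
        if seq.length < 1:
            raise ValidationError("empty token sequence")
        x = seq.tokens
        for layer in self.encoder:
            x = layer(x)
        pred = x[:, -1, :]  # prediction token output
        return self.head(pred).reshape(x.shape[0])

    def forward(self, himg, vimg, preop_va, indices) -> Tensor:
        return self.fuse(self.encode_tokens(himg, vimg, preop_va, indices))


# ---- functional surface ------------------------------------------------


def extract_image_features(
    img: BScanImage | np.ndarray, backbone: ConvBackbone | None = None, seed: int = 0
) -> np.ndarray:
    """Flatten one B-scan into the backbone's 512-dim feature vector.

    With ``backbone=None`` a randomly initialized (seeded) backbone is
    used; in the trained pipeline the model's own backbone is passed in.
    """
    arr = img.pixels if isinstance(img, BScanImage) else np.asarray(img, dtype=float)
    if arr.ndim != 2 or arr.size == 0 or not np.all(np.isfinite(arr)):
        raise ValidationError("image must be a finite non-empty 2-D array")
    if backbone is None:
        backbone = ConvBackbone(np.random.default_rng(seed))
    x = _prepare_image(arr, size=64)
    out = backbone(Tensor(x[None, None]))
    return out.data[0]


def encode_tokens(
    net: VAFusionNet,
    himg: np.ndarray | None = None,
    vimg: np.ndarray | None = None,
    preop_va: np.ndarray | None = None,
    indices: np.ndarray | None = None,
) -> TokenSequence:
    """Encode per-modality inputs into the fused token sequence."""

    def _t(a, shape2):
        if a is None:
            return None
        a = np.asarray(a, dtype=float)
        return Tensor(a.reshape(shape2) if a.ndim != len(shape2) else a)

    return net.encode_tokens(
        None if himg is None else Tensor(np.asarray(himg, dtype=float)),
        None if vimg is None else Tensor(np.asarray(vimg, dtype=float)),
        _t(preop_va, (-1, 1)),
        _t(indices, (-1, N_INDICES)),
    )


def transformer_fuse(net: VAFusionNet, seq: TokenSequence) -> np.ndarray:
    """Run the encoder stack and return the prediction-head scalars."""
    return net.fuse(seq).data


def split_dataset(records: list, fractions=(0.6, 0.2, 0.2), seed: int = 0):
    """Random, seeded, disjoint and exhaustive train/validation/test split.

    Sizes are ``round(f * n)`` for the first two fractions with the
    remainder as the test set, matching the convention that a 60/20/20
    split of 2,051 eyes yields 1,231/410/410.
    """
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError("fractions must be three values summing to 1")
    n = len(records)
    n_train = round(fractions[0] * n)
    n_val = round(fractions[1] * n)
    if n_train + n_val > n:
        raise ValidationError("fractions leave no room for a test set")
    order = np.random.default_rng(seed).permutation(n)
    pick = lambda idx: [records[i] for i in idx]
    return (
        pick(order[:n_train]),
        pick(order[n_train : n_train + n_val]),
        pick(order[n_train + n_val :]),
    )


# ---- data preparation --------------------------------------------------


def _prepare_image(arr: np.ndarray, size: int) -> np.ndarray:
    """Resize to size x size and map intensities to roughly [-0.5, 0.5]."""
    if arr.shape != (size, size):
        arr = resize(arr, (size, size), anti_aliasing=True, preserve_range=True)
    return arr / 255.0 - 0.5


def _record_image(rec: CohortRecord, which: str) -> np.ndarray:
    img = rec.extras.get(which)
    if isinstance(img, BScanImage):
        return img.pixels
    path = rec.himg_path if which == "himg" else rec.vimg_path
    if path is None:
        raise ConfigurationError(f"record {rec.eye_id} lacks required image {which!r}")
    return load_image(path, rec.device_id, "horizontal" if which == "himg" else "vertical").pixels


@dataclass
class _Arrays:
    himg: np.ndarray | None
    vimg: np.ndarray | None
    preop: np.ndarray | None
    indices: np.ndarray | None
    y: np.ndarray | None
    eye_ids: list[str]


def _collect(records: list[CohortRecord], variant: ModelVariant, cfg: TrainConfig,
             require_labels: bool) -> _Arrays:
    n = len(records)
    size = cfg.image_size
    himg = np.empty((n, 1, size, size)) if variant.uses_himg else None
    vimg = np.empty((n, 1, size, size)) if variant.uses_vimg else None
    preop = np.empty((n, 1)) if variant.uses_preop_va else None
    idx = np.empty((n, N_INDICES)) if variant.uses_indices else None
    y = np.empty(n)
    for i, rec in enumerate(records):
        if variant.uses_himg:
            himg[i, 0] = _prepare_image(_record_image(rec, "himg"), size)
        if variant.uses_vimg:
            vimg[i, 0] = _prepare_image(_record_image(rec, "vimg"), size)
        if variant.uses_preop_va:
            preop[i, 0] = rec.preop_bcva
        if variant.uses_indices:
            if rec.indices is None:
                raise ConfigurationError(
                    f"variant {variant.id} requires morphological indices, "
                    f"missing on eye {rec.eye_id}"
                )
            idx[i] = np.asarray(rec.indices, dtype=float)
        if rec.postop_bcva is None:
            if require_labels:
                raise TrainingError(f"eye {rec.eye_id} lacks a postoperative BCVA label")
            y[i] = np.nan
        else:
            y[i] = rec.postop_bcva
    return _Arrays(himg, vimg, preop, idx, y, [r.eye_id for r in records])


@dataclass
class _Standardizer:
    """Z-score statistics for the scalar modalities, fit on the train set."""

    preop_mean: float = 0.0
    preop_sd: float = 1.0
    idx_mean: np.ndarray = field(default_factory=lambda: np.zeros(N_INDICES))
    idx_sd: np.ndarray = field(default_factory=lambda: np.ones(N_INDICES))

    @classmethod
    def fit(cls, arrs: _Arrays) -> "_Standardizer":
        s = cls()
        if arrs.preop is not None:
            s.preop_mean = float(arrs.preop.mean())
            s.preop_sd = float(max(arrs.preop.std(), 1e-6))
        if arrs.indices is not None:
            s.idx_mean = arrs.indices.mean(axis=0)
            s.idx_sd = np.maximum(arrs.indices.std(axis=0), 1e-6)
        return s

    def apply(self, arrs: _Arrays) -> _Arrays:
        preop = None if arrs.preop is None else (arrs.preop - self.preop_mean) / self.preop_sd
        idx = None if arrs.indices is None else (arrs.indices - self.idx_mean) / self.idx_sd
        return _Arrays(arrs.himg, arrs.vimg, preop, idx, arrs.y, arrs.eye_ids)


@dataclass
class TrainedModel:
    """A trained fusion model: network, config and train-set statistics."""

    net: VAFusionNet
    variant: ModelVariant
    cfg: TrainConfig
    standardizer: _Standardizer
    log: list[dict]
    best_val_mae: float


def _forward_batch(net: VAFusionNet, arrs: _Arrays, sel: np.ndarray) -> Tensor:
    pick = lambda a: None if a is None else Tensor(a[sel])
    return net.forward(pick(arrs.himg), pick(arrs.vimg), pick(arrs.preop), pick(arrs.indices))


def _predict_arrays(net: VAFusionNet, arrs: _Arrays, batch: int = 64) -> np.ndarray:
    n = len(arrs.eye_ids)
    out = np.empty(n)
    for lo in range(0, n, batch):
        sel = np.arange(lo, min(lo + batch, n))
        out[sel] = _forward_batch(net, arrs, sel).data
    return out


def train_model(
    variant: ModelVariant | str,
    train_records: list[CohortRecord],
    val_records: list[CohortRecord],
    cfg: TrainConfig | None = None,
) -> TrainedModel:
    """Train one variant with SGD on the RMSE loss.

    Per epoch: shuffle, minibatch forward/backward, SGD step at the
    scheduled learning rate; then validation MAE. The parameters with the
    best validation MAE are restored into the returned model. Fully
    deterministic given ``cfg.seed``.
    """
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    cfg = cfg or TrainConfig()
    if not train_records:
        raise TrainingError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    net = VAFusionNet(variant, cfg, rng)
    tr = _collect(train_records, variant, cfg, require_labels=True)
    va = _collect(val_records, variant, cfg, require_labels=True)
    std = _Standardizer.fit(tr)
    tr, va = std.apply(tr), std.apply(va)

    opt = SGD(
        net.parameters(),
        lr=cfg.lr0,
        momentum=cfg.momentum,
        decay=cfg.lr_decay,
        step_epochs=cfg.lr_step_epochs,
    )
    n = len(train_records)
    best_state = net.state()
    best_mae = math.inf
    best_epoch = -1
    log: list[dict] = []
    for epoch in range(cfg.max_epochs):
        lr = opt.set_epoch(epoch)
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            sel = order[lo : lo + cfg.batch_size]
            opt.zero_grad()
            pred = _forward_batch(net, tr, sel)
            err = pred - Tensor(tr.y[sel])
            loss = (err * err).mean().sqrt()  # RMSE loss
            if not np.isfinite(loss.data):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_pred = _predict_arrays(net, va)
        val_mae = float(np.mean(np.abs(val_pred - va.y))) if len(va.eye_ids) else math.nan
        log.append(
            {
                "epoch": epoch,
                "lr": lr,
                "train_rmse": float(np.mean(losses)),
                "val_mae": val_mae,
            }
        )
        if val_mae < best_mae:
            best_mae = val_mae
            best_state = net.state()
            best_epoch = epoch
        elif cfg.patience is not None and epoch - best_epoch >= cfg.patience:
            break
    net.load_state(best_state)
    return TrainedModel(
        net=net, variant=variant, cfg=cfg, standardizer=std, log=log, best_val_mae=best_mae
    )


def predict(model: TrainedModel, records: list[CohortRecord] | CohortRecord) -> np.ndarray:
    """Predict postoperative BCVA (logMAR) for one or more records."""
    single = isinstance(records, CohortRecord)
    recs = [records] if single else list(records)
    arrs = model.standardizer.apply(
        _collect(recs, model.variant, model.cfg, require_labels=False)
    )
    out = _predict_arrays(model.net, arrs)
    return out if not single else float(out[0])
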