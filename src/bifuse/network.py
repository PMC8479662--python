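"""The prognosis classifier: bilinear encoders feeding a multi-layer network.

The model maps a pair of per-patient feature vectors (genomic g, image p, each
of length L after selection) to a probability of being a shorter-term (< 5
year) survivor.  Depending on the variant, the classifier input is the raw
vectors, within-modality bilinear features, cross-modality bilinear features,
or the full fused vector

    h = (g (+) f_intra_g) (+) f_inter (+) (p (+) f_intra_p),   |h| = K + 2M + 2L.

The classifier is S fully connected ReLU layers with dropout, topped by a
two-unit softmax; training minimizes binary cross-entropy with Adam over
shuffled mini-batches.  Forward, backward and the optimizer are implemented
directly in numpy, so every arithmetic step is explicit, deterministic under
a seed, and runs identically on any CPU.

Because every encoder is a dense map over a fixed transform of the inputs
(identity or a flattened outer product), training precomputes those
transforms once per dataset and then performs pure dense-layer passes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .bilinear import init_bilinear_params, outer_flatten, BilinearParams

__all__ = [
    "VARIANTS",
    "ModelConfig",
    "PrognosisModel",
    "PredictionSet",
    "build_model",
    "forward",
    "bce_loss",
    "train",
    "predict",
]

# Each variant wires a list of encoder blocks whose outputs are concatenated
# into the classifier input.  A block is ("raw", src) passing one modality
# through, or ("bilinear", a, b, dim_key) — a ReLU dense map over
# vec(a b^T) with output width config.k or config.m.
VARIANTS: dict[str, list[tuple]] = {
    "baseline_g": [("raw", "g")],
    "intra_g": [("raw", "g"), ("bilinear", "g", "g", "m")],
    "baseline_p": [("raw", "p")],
    "intra_p": [("raw", "p"), ("bilinear", "p", "p", "m")],
    "baseline_gp": [("raw", "g"), ("raw", "p")],
    "inter_only": [("bilinear", "g", "p", "k")],
    "full_fusion": [
        ("raw", "g"),
        ("bilinear", "g", "g", "m"),
        ("bilinear", "g", "p", "k"),
        ("raw", "p"),
        ("bilinear", "p", "p", "m"),
    ],
}


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults are the reference operating point: L=32 selected features per
    modality, K=20 cross-modality and M=20 within-modality bilinear features,
    S=4 hidden layers of widths 500/256/128/32 with dropout 0.3/0.3/0.1/0.1,
    Adam at learning rate 4e-4, 150 epochs, batch size 16.
    """

    variant: str = "full_fusion"
    l: int = 32
    k: int = 20
    m: int = 20
    s: int = 4
    widths: tuple[int, ...] = (500, 256, 128, 32)
    dropout: tuple[float, ...] = (0.3, 0.3, 0.1, 0.1)
    learning_rate: float = 4e-4
    epochs: int = 150
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; choose from {sorted(VARIANTS)}"
            )
        self.widths = tuple(int(w) for w in self.widths)
        self.dropout = tuple(float(d) for d in self.dropout)
        if len(self.widths) != self.s or len(self.dropout) != self.s:
            raise ValueError("widths and dropout must each have S entries")
        if any(not (0 <= d < 1) for d in self.dropout):
            raise ValueError("dropout rates must be in [0, 1)")
        if min(self.l, self.k, self.m) < 1 or min(self.widths) < 1:
            raise ValueError("all dimensions must be >= 1")


@dataclass
class _Block:
    kind: str           # "raw" | "bilinear"
    a: str              # "g" | "p"
    b: str | None
    out_dim: int
    name: str


def _blocks_for(config: ModelConfig) -> list[_Block]:
    blocks = []
    for idx, spec in enumerate(VARIANTS[config.variant]):
        if spec[0] == "raw":
            blocks.append(_Block("raw", spec[1], None, config.l, f"raw{idx}_{spec[1]}"))
        else:
            _, a, b, dim_key = spec
            out = config.k if dim_key == "k" else config.m
            blocks.append(_Block("bilinear", a, b, out, f"bil{idx}_{a}{b}"))
    return blocks


@dataclass
class PrognosisModel:
    """A (possibly trained) prognosis classifier for one variant."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    trained: bool = False
    history: list[float] = field(default_factory=list)

    @property
    def blocks(self) -> list[_Block]:
        return _blocks_for(self.config)

    @property
    def input_width(self) -> int:
        return sum(b.out_dim for b in self.blocks)

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def encoder_params(self, block_name: str) -> BilinearParams:
        """The bilinear-encoder weights of one block, as an order-3 tensor."""
        for blk in self.blocks:
            if blk.name == block_name and blk.kind == "bilinear":
                la = self.config.l
                w = self.params[f"{blk.name}_W"].reshape(blk.out_dim, la, la)
                return BilinearParams(weights=w, bias=self.params[f"{blk.name}_b"])
        raise KeyError(f"no bilinear block named {block_name!r}")

    def encode(self, g: np.ndarray, p: np.ndarray) -> np.ndarray:
        """The concatenated classifier input (the fused h for the full variant)."""
        xs = _block_inputs(self.blocks, np.atleast_2d(g), np.atleast_2d(p))
        parts = _encode_blocks(self.params, self.blocks, xs)
        z = np.concatenate(parts, axis=1)
        return z[0] if np.asarray(g).ndim == 1 else z


def _glorot(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_out, fan_in))


def build_model(config: ModelConfig) -> PrognosisModel:
    """Construct an untrained model with seeded Glorot-uniform initialization."""
    rng = np.random.default_rng(config.seed)
    params: dict[str, np.ndarray] = {}
    blocks = _blocks_for(config)
    for blk in blocks:
        if blk.kind == "bilinear":
            bp = init_bilinear_params(blk.out_dim, config.l, config.l, rng)
            params[f"{blk.name}_W"] = bp.matrix.copy()
            params[f"{blk.name}_b"] = bp.bias.copy()
    fan_in = sum(b.out_dim for b in blocks)
    for s, width in enumerate(config.widths, start=1):
        params[f"fc{s}_W"] = _glorot(rng, width, fan_in)
        params[f"fc{s}_b"] = np.zeros(width)
        fan_in = width
    params["out_W"] = _glorot(rng, 2, fan_in)
    params["out_b"] = np.zeros(2)
    return PrognosisModel(config=config, params=params)


def _block_inputs(blocks: list[_Block], G: np.ndarray, P: np.ndarray) -> list[np.ndarray]:
    """Fixed per-block input transforms (identity or flattened outer product)."""
    xs = []
    for blk in blocks:
        if blk.kind == "raw":
            xs.append(G if blk.a == "g" else P)
        else:
            a = G if blk.a == "g" else P
            b = G if blk.b == "g" else P
            xs.append(outer_flatten(a, b))
    return xs


def _encode_blocks(params, blocks, xs) -> list[np.ndarray]:
    parts = []
    for blk, x in zip(blocks, xs):
        if blk.kind == "raw":
            parts.append(x)
        else:
            pre = x @ params[f"{blk.name}_W"].T + params[f"{blk.name}_b"]
            parts.append(np.maximum(pre, 0.0))
    return parts


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward_batch(
    params: dict[str, np.ndarray],
    config: ModelConfig,
    blocks: list[_Block],
    xs: list[np.ndarray],
    train_mode: bool,
    rng: np.random.Generator | None,
):
    """Full forward pass; returns probabilities and the cache for backprop."""
    parts = _encode_blocks(params, blocks, xs)
    z = np.concatenate(parts, axis=1)
    cache = {"xs": xs, "parts": parts, "z": z, "acts": [], "masks": []}
    o = z
    for s in range(1, config.s + 1):
        pre = o @ params[f"fc{s}_W"].T + params[f"fc{s}_b"]
        o = np.maximum(pre, 0.0)
        if train_mode and config.dropout[s - 1] > 0:
            rate = config.dropout[s - 1]
            mask = (rng.random(o.shape) >= rate).astype(o.dtype) / (1.0 - rate)
            o = o * mask
            cache["masks"].append(mask)
        else:
            cache["masks"].append(None)
        cache["acts"].append(o)
    logits = o @ params["out_W"].T + params["out_b"]
    probs = _softmax(logits)
    cache["probs"] = probs
    return probs, cache


def _backward_batch(
    params: dict[str, np.ndarray],
    config: ModelConfig,
    blocks: list[_Block],
    cache: dict,
    labels: np.ndarray,
) -> dict[str, np.ndarray]:
    """Gradients of mean cross-entropy w.r.t. every parameter."""
    n = len(labels)
    probs = cache["probs"]
    onehot = np.zeros_like(probs)
    onehot[np.arange(n), labels] = 1.0
    dlogits = (probs - onehot) / n
    grads: dict[str, np.ndarray] = {}
    top = cache["acts"][-1] if config.s > 0 else cache["z"]
    grads["out_W"] = dlogits.T @ top
    grads["out_b"] = dlogits.sum(axis=0)
    d = dlogits @ params["out_W"]
    for s in range(config.s, 0, -1):
        o = cache["acts"][s - 1]
        mask = cache["masks"][s - 1]
        if mask is not None:
            d = d * mask
            o_pre_drop = o / np.where(mask == 0, 1.0, mask)  # undo inverted dropout
            d = d * (o_pre_drop > 0)
        else:
            d = d * (o > 0)
        below = cache["acts"][s - 2] if s >= 2 else cache["z"]
        grads[f"fc{s}_W"] = d.T @ below
        grads[f"fc{s}_b"] = d.sum(axis=0)
        d = d @ params[f"fc{s}_W"]
    # split the concatenated-input gradient across encoder blocks
    offset = 0
    for blk, x, part in zip(blocks, cache["xs"], cache["parts"]):
        d_part = d[:, offset : offset + blk.out_dim]
        offset += blk.out_dim
        if blk.kind == "bilinear":
            d_pre = d_part * (part > 0)
            grads[f"{blk.name}_W"] = d_pre.T @ x
            grads[f"{blk.name}_b"] = d_pre.sum(axis=0)
    return grads


def forward(
    model: PrognosisModel,
    g: np.ndarray,
    p: np.ndarray,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Probability pairs [P(y=0), P(y=1)] per sample.

    With ``train_mode=False`` (dropout off) this is a pure function of the
    inputs; ``train_mode=True`` requires an rng for dropout masks.
    """
    g2 = np.atleast_2d(np.asarray(g, dtype=float))
    p2 = np.atleast_2d(np.asarray(p, dtype=float))
    if train_mode and rng is None:
        raise ValueError("train_mode forward needs an rng for dropout")
    xs = _block_inputs(model.blocks, g2, p2)
    probs, _ = _forward_batch(model.params, model.config, model.blocks, xs, train_mode, rng)
    return probs[0] if np.asarray(g).ndim == 1 else probs


def bce_loss(scores: np.ndarray, labels: np.ndarray, clip: float = 1e-12) -> float:
    """Binary cross-entropy, L = -(1/N) sum [y ln P + (1-y) ln(1-P)]."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError(f"shape mismatch: scores {scores.shape}, labels {labels.shape}")
    p = np.clip(scores, clip, 1.0 - clip)
    return float(-np.mean(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p)))


def train(
    model: PrognosisModel,
    g_matrix: np.ndarray,
    p_matrix: np.ndarray,
    labels: np.ndarray,
    config: ModelConfig | None = None,
) -> PrognosisModel:
    """Train with Adam over shuffled mini-batches; reproducible under the seed.

    Adam uses the conventional moments (0.9, 0.999, eps 1e-8) at the
    configured learning rate; mini-batches are reshuffled every epoch; the
    final epoch's weights are kept (no early stopping).  Arithmetic runs in
    single precision (the convention of GPU frameworks) with in-place
    moment updates; results remain bit-reproducible under the seed.
    """
    config = config or model.config
    dtype = np.float32
    G = np.atleast_2d(np.asarray(g_matrix, dtype=dtype))
    P = np.atleast_2d(np.asarray(p_matrix, dtype=dtype))
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if G.shape[0] != n or P.shape[0] != n:
        raise ValueError("feature matrices and labels must be aligned")
    if len(np.unique(y)) < 2:
        warnings.warn("training labels contain a single class", stacklevel=2)

    rng = np.random.default_rng(config.seed)
    blocks = model.blocks
    xs_full = _block_inputs(blocks, G, P)  # precomputed once; pure dense training after

    # all parameters live in one contiguous buffer; the per-tensor dict holds
    # views into it, so the Adam update is a few whole-buffer operations
    keys = list(model.params.keys())
    shapes = {k: model.params[k].shape for k in keys}
    slices: dict[str, slice] = {}
    offset = 0
    for k in keys:
        size = int(np.prod(shapes[k]))
        slices[k] = slice(offset, offset + size)
        offset += size
    pflat = np.empty(offset, dtype=dtype)
    for k in keys:
        pflat[slices[k]] = model.params[k].ravel()
    params = {k: pflat[slices[k]].reshape(shapes[k]) for k in keys}

    beta1, beta2, eps = 0.9, 0.999, 1e-8
    gflat = np.empty_like(pflat)
    mstate = np.zeros_like(pflat)
    vstate = np.zeros_like(pflat)
    denom = np.empty_like(pflat)
    t = 0
    history: list[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        xs_epoch = [x[order] for x in xs_full]  # batches below are cheap views
        y_epoch = y[order]
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            stop = start + config.batch_size
            xs = [x[start:stop] for x in xs_epoch]
            yb = y_epoch[start:stop]
            probs, cache = _forward_batch(params, config, blocks, xs, True, rng)
            loss = bce_loss(probs[:, 1], yb)
            epoch_loss += loss * len(yb)
            grads = _backward_batch(params, config, blocks, cache, yb)
            for k in keys:
                gflat[slices[k]] = grads[k].ravel()
            t += 1
            # bias-corrected step folded into the rate: alpha_t * m / (sqrt(v) + eps_t)
            alpha_t = config.learning_rate * np.sqrt(1 - beta2**t) / (1 - beta1**t)
            eps_t = eps * np.sqrt(1 - beta2**t)
            mstate *= beta1
            mstate += (1 - beta1) * gflat
            np.square(gflat, out=gflat)
            vstate *= beta2
            vstate += (1 - beta2) * gflat
            np.sqrt(vstate, out=denom)
            denom += eps_t
            np.divide(mstate, denom, out=denom)
            denom *= alpha_t
            pflat -= denom
        history.append(epoch_loss / n)
    params = {k: params[k].copy() for k in keys}
    return PrognosisModel(config=replace(config), params=params, trained=True, history=history)


def save_model(model: PrognosisModel, path) -> None:
    """Checkpoint parameters and config; shapes are recorded per tensor name."""
    meta = dict(model.config.__dict__)
    meta["trained"] = model.trained
    np.savez(
        path,
        __meta__=np.frombuffer(repr(meta).encode(), dtype=np.uint8),
        __history__=np.asarray(model.history, dtype=float),
        **model.params,
    )


def load_model(path) -> PrognosisModel:
    import ast

    with np.load(path) as data:
        meta = ast.literal_eval(bytes(data["__meta__"]).decode())
        trained = bool(meta.pop("trained"))
        history = data["__history__"].tolist()
        params = {k: data[k] for k in data.files if not k.startswith("__")}
    return PrognosisModel(
        config=ModelConfig(**meta), params=params, trained=trained, history=history
    )


@dataclass
class PredictionSet:
    """Out-of-sample scores: one P(shorter-term) per patient."""

    patient_ids: list[str]
    scores: np.ndarray
    labels: np.ndarray
    folds: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.folds = np.asarray(self.folds, dtype=int)
        if not ((self.scores >= 0) & (self.scores <= 1)).all():
            raise ValueError("scores must lie in [0, 1]")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("duplicate patient id in prediction set")


def predict(
    model: PrognosisModel,
    g_matrix: np.ndarray,
    p_matrix: np.ndarray,
    patient_ids: list[str] | None = None,
    labels: np.ndarray | None = None,
    fold: int = 0,
) -> PredictionSet:
    """Deterministic inference (dropout off): P(y=1) per sample."""
    if not model.trained:
        raise ValueError("model has not been trained")
    probs = forward(model, np.atleast_2d(g_matrix), np.atleast_2d(p_matrix), train_mode=False)
    scores = probs[:, 1]
    n = len(scores)
    if patient_ids is None:
        patient_ids = [str(i) for i in range(n)]
    if labels is None:
        labels = np.zeros(n, dtype=int)
    return PredictionSet(
        patient_ids=list(patient_ids),
        scores=scores,
        labels=labels,
        folds=np.full(n, fold, dtype=int),
    )
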