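"""Bilinear feature encoding: the multiplicative-interaction core of the model.

An encoder maps a pair of feature vectors (a, b) to
``f_k = ReLU(sum_ij w_ijk a_i b_j + c_k)`` — a dense layer over the flattened
outer product ``vec(a b^T)``.  The cross-modality encoder takes the genomic
and image vectors (a=g, b=p); each within-modality encoder takes one vector
against itself (a=b=x), so its pre-activation is a quadratic form in x.

Two forward paths are provided: the vectorized path used everywhere, and a
literal double-sum path kept as an independent numerical oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BilinearParams",
    "EncodedFeatures",
    "outer_flatten",
    "inter_bfem_forward",
    "inter_bfem_forward_naive",
    "intra_bfem_forward",
    "intra_bfem_forward_naive",
    "intra_output",
    "fuse",
    "inter_param_count",
    "intra_param_count",
    "init_bilinear_params",
]


@dataclass
class BilinearParams:
    """Weights of one bilinear encoder.

    ``weights`` has shape (out_dim, in_dim_a, in_dim_b): slice k is the
    interaction matrix producing output k.  ``bias`` has length out_dim.
    """

    weights: np.ndarray
    bias: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.weights.ndim != 3:
            raise ValueError(f"weights must be an order-3 tensor, got ndim={self.weights.ndim}")
        if self.bias.shape != (self.weights.shape[0],):
            raise ValueError(
                f"bias length {self.bias.shape} does not match out_dim {self.weights.shape[0]}"
            )
        if not (np.isfinite(self.weights).all() and np.isfinite(self.bias).all()):
            raise ValueError("bilinear parameters must be finite")

    @property
    def out_dim(self) -> int:
        return self.weights.shape[0]

    @property
    def in_dims(self) -> tuple[int, int]:
        return self.weights.shape[1], self.weights.shape[2]

    @property
    def matrix(self) -> np.ndarray:
        """Weights flattened to (out_dim, in_a*in_b), row-major over (i, j)."""
        return self.weights.reshape(self.out_dim, -1)

    def n_params(self) -> int:
        return self.weights.size + self.bias.size


@dataclass
class EncodedFeatures:
    """All encoder outputs for one sample, plus the fused vector h."""

    f_inter: np.ndarray
    f_intra_g: np.ndarray
    f_intra_p: np.ndarray
    f_hat_g: np.ndarray
    f_hat_p: np.ndarray
    h: np.ndarray


def outer_flatten(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-major flattening of the outer product a b^T.

    Entry ``i*len(b) + j`` equals ``a[i] * b[j]``.  Accepts a batch as 2-D
    arrays (samples x features), returning (samples, La*Lb).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("cannot take the outer product with an empty vector")
    if a.ndim == 1 and b.ndim == 1:
        return np.outer(a, b).reshape(-1)
    a2 = np.atleast_2d(a)
    b2 = np.atleast_2d(b)
    if a2.shape[0] != b2.shape[0]:
        raise ValueError(f"batch sizes differ: {a2.shape[0]} vs {b2.shape[0]}")
    return (a2[:, :, None] * b2[:, None, :]).reshape(a2.shape[0], -1)


def _check_lengths(params: BilinearParams, a: np.ndarray, b: np.ndarray) -> None:
    la, lb = params.in_dims
    if a.shape[-1] != la or b.shape[-1] != lb:
        raise ValueError(
            f"input lengths ({a.shape[-1]}, {b.shape[-1]}) do not match "
            f"encoder dimensions ({la}, {lb})"
        )


def inter_bfem_forward(params: BilinearParams, g: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Cross-modality bilinear features: ReLU(W vec(g p^T) + b).

    Vectorized path; supports a batch when g, p are 2-D.
    """
    g = np.asarray(g, dtype=float)
    p = np.asarray(p, dtype=float)
    _check_lengths(params, g, p)
    x = outer_flatten(g, p)
    pre = x @ params.matrix.T + params.bias
    return np.maximum(pre, 0.0)


def inter_bfem_forward_naive(params: BilinearParams, g: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Literal double-sum form, f_k = ReLU(sum_i sum_j w_ijk g_i p_j + b_k).

    Testing oracle only — must agree with the vectorized path to 1e-9.
    """
    g = np.asarray(g, dtype=float)
    p = np.asarray(p, dtype=float)
    if g.ndim != 1 or p.ndim != 1:
        raise ValueError("the naive path takes single samples only")
    _check_lengths(params, g, p)
    k_dim = params.out_dim
    out = np.empty(k_dim)
    for k in range(k_dim):
        acc = 0.0
        for i in range(len(g)):
            for j in range(len(p)):
                acc += params.weights[k, i, j] * g[i] * p[j]
        out[k] = max(acc + params.bias[k], 0.0)
    return out


def intra_bfem_forward(params: BilinearParams, x: np.ndarray) -> np.ndarray:
    """Within-modality bilinear features: ReLU(W vec(x x^T) + b)."""
    la, lb = params.in_dims
    if la != lb:
        raise ValueError(f"within-modality encoder needs square slices, got ({la}, {lb})")
    return inter_bfem_forward(params, x, x)


def intra_bfem_forward_naive(params: BilinearParams, x: np.ndarray) -> np.ndarray:
    return inter_bfem_forward_naive(params, x, x)


def intra_output(x: np.ndarray, f_intra: np.ndarray) -> np.ndarray:
    """Concatenate the raw modality vector with its bilinear features: x (+) f."""
    x = np.asarray(x, dtype=float)
    f_intra = np.asarray(f_intra, dtype=float)
    return np.concatenate([x, f_intra], axis=-1)


def fuse(f_hat_g: np.ndarray, f_inter: np.ndarray, f_hat_p: np.ndarray) -> np.ndarray:
    """Fused representation h = f_hat_g (+) f_inter (+) f_hat_p.

    With the default dimensions (L=32, K=20, M=20) the result has length
    K + 2M + 2L = 124.
    """
    return np.concatenate([f_hat_g, f_inter, f_hat_p], axis=-1)


def inter_param_count(k: int, l: int) -> int:
    """Trainable-parameter count of a cross-modality encoder: K*(L*L + 1)."""
    if k < 1 or l < 1:
        raise ValueError(f"dimensions must be >= 1, got K={k}, L={l}")
    return k * (l * l + 1)


def intra_param_count(m: int, l: int) -> int:
    """Trainable-parameter count of a within-modality encoder: M*(L*L + 1)."""
    if m < 1 or l < 1:
        raise ValueError(f"dimensions must be >= 1, got M={m}, L={l}")
    return m * (l * l + 1)


def init_bilinear_params(
    out_dim: int, in_a: int, in_b: int, rng: np.random.Generator
) -> BilinearParams:
    """Glorot-uniform initialization over the flattened (out, in_a*in_b) map."""
    fan_in = in_a * in_b
    limit = np.sqrt(6.0 / (fan_in + out_dim))
    weights = rng.uniform(-limit, limit, size=(out_dim, in_a, in_b))
    return BilinearParams(weights=weights, bias=np.zeros(out_dim))
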