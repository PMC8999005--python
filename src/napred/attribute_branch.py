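"""Second branch: pairwise node-attribute embedding and CAE encoding.

For a drug i and disease j, the attribute embedding P stacks row i and row
N_r+j of each heterogeneous network U^m into a (2, N_r+N_d, 3) tensor: the
drug row holds i's similarities to all drugs and associations to all
diseases, the disease row the mirror image.  A convolutional autoencoder
(two conv+max-pool encoder layers, three transposed-conv decoder layers)
is pretrained to reconstruct P; its bottleneck code, flattened, feeds a
softmax head for the branch-2 association probability.

Internally the three networks are treated as channels, the two rows as
image height and the N_r+N_d node axis as width (NCHW layout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .topology_branch import softmax_np, _glorot

__all__ = [
    "ConvSpec", "TConvSpec", "CAEConfig", "build_attribute_embedding",
    "embedding_to_nchw", "cae_encode", "cae_decode", "reconstruction_loss",
    "branch2_score", "ConvAutoencoderBranch",
]


@dataclass(frozen=True)
class ConvSpec:
    """One encoder layer: stride-1 conv (+ReLU) followed by stride-1 max-pool."""

    out_channels: int
    kernel: tuple[int, int] = (2, 2)
    pad: int = 1
    pool: tuple[int, int] = (2, 2)


@dataclass(frozen=True)
class TConvSpec:
    """One decoder layer: stride-1 transposed convolution (+ReLU, last linear)."""

    out_channels: int
    kernel: tuple[int, int] = (2, 2)
    pad: int = 0


def _default_encoder():
    return [ConvSpec(8), ConvSpec(16)]


def _default_decoder():
    # shapes: (2,W) -> (3,W+1) -> (2,W) -> (2,W); channels 16 -> 8 -> 4 -> 3
    return [TConvSpec(8, (2, 2), 0), TConvSpec(4, (2, 2), 1),
            TConvSpec(3, (3, 3), 1)]


@dataclass
class CAEConfig:
    """Encoder/decoder layer specs; smallest geometry with 2+3 hidden layers."""

    encoder: list[ConvSpec] = field(default_factory=_default_encoder)
    decoder: list[TConvSpec] = field(default_factory=_default_decoder)


def build_attribute_embedding(U1, U2, U3, i: int, j: int) -> np.ndarray:
    """Pair attribute tensor P of shape (2, N_r+N_d, 3).

    Slice (0, :, m-1) is row i of U^m, slice (1, :, m-1) row N_r+j of U^m.
    """
    nets = (U1, U2, U3)
    n_r, n_d = U1.n_drugs, U1.n_diseases
    if not (0 <= i < n_r):
        raise IndexError(f"drug index {i} out of range [0,{n_r})")
    if not (0 <= j < n_d):
        raise IndexError(f"disease index {j} out of range [0,{n_d})")
    P = np.empty((2, n_r + n_d, 3))
    for m, U in enumerate(nets):
        P[0, :, m] = U.values[i]
        P[1, :, m] = U.values[n_r + j]
    return P


def embedding_to_nchw(P: np.ndarray) -> np.ndarray:
    """(…, 2, N, 3) embedding -> (…, 3, 2, N) channels-first layout."""
    return np.moveaxis(np.asarray(P, dtype=float), -1, -3)


def reconstruction_loss(P_batch, P_hat_batch) -> float:
    """Mean over samples of the squared Frobenius distance ||P_n - P̂_n||²."""
    P_batch = np.asarray(P_batch, dtype=float)
    P_hat_batch = np.asarray(P_hat_batch, dtype=float)
    if P_batch.shape != P_hat_batch.shape:
        raise ValueError(
            f"shape mismatch {P_batch.shape} vs {P_hat_batch.shape}")
    if P_batch.shape[0] == 0:
        raise ValueError("empty batch")
    diff = (P_batch - P_hat_batch).reshape(P_batch.shape[0], -1)
    return float(np.mean((diff ** 2).sum(axis=1)))


def branch2_score(code, W, b) -> np.ndarray:
    """Softmax head over the flattened bottleneck code."""
    return softmax_np(np.asarray(W) @ np.asarray(code, dtype=float).reshape(-1)
                      + np.asarray(b))


class ConvAutoencoderBranch:
    """Trainable CAE + softmax head over pair attribute embeddings.

    ``input_shape`` is the channels-first shape (3, 2, N_r+N_d).  The
    decoder geometry is validated at construction: a configuration whose
    traced output shape differs from the input shape raises ValueError.
    """

    def __init__(self, input_shape, config: CAEConfig | None = None, seed=0):
        self.input_shape = tuple(input_shape)
        self.config = config or CAEConfig()
        rng = np.random.default_rng(seed)
        p = {}
        c, h, w = self.input_shape
        for t, spec in enumerate(self.config.encoder, start=1):
            kh, kw = spec.kernel
            p[f"W_enc_{t}"] = _glorot(rng, (spec.out_channels, c, kh, kw))
            p[f"b_enc_{t}"] = Tensor(np.zeros(spec.out_channels),
                                     requires_grad=True)
            h = h + 2 * spec.pad - kh + 1
            w = w + 2 * spec.pad - kw + 1
            if h < 1 or w < 1:
                raise ValueError(f"encoder layer {t} collapses the map: "
                                 f"({h},{w})")
            h = h - spec.pool[0] + 1
            w = w - spec.pool[1] + 1
            if h < 1 or w < 1:
                raise ValueError(f"encoder pool {t} collapses the map")
            c = spec.out_channels
        self.code_shape = (c, h, w)
        self.code_len = c * h * w
        for l, spec in enumerate(self.config.decoder, start=1):
            kh, kw = spec.kernel
            p[f"W_dec_{l}"] = _glorot(rng, (c, spec.out_channels, kh, kw))
            p[f"b_dec_{l}"] = Tensor(np.zeros(spec.out_channels),
                                     requires_grad=True)
            h = h + kh - 1 - 2 * spec.pad
            w = w + kw - 1 - 2 * spec.pad
            c = spec.out_channels
        if (c, h, w) != self.input_shape:
            raise ValueError(
                f"decoder output shape {(c, h, w)} does not reproduce the "
                f"input shape {self.input_shape}; adjust kernels/paddings")
        p["W_soft2"] = _glorot(rng, (2, self.code_len))
        p["b_soft2"] = Tensor(np.zeros(2), requires_grad=True)
        self.params = p

    # -- graph-building forward passes ------------------------------------

    def encode(self, x: Tensor) -> Tensor:
        for t, spec in enumerate(self.config.encoder, start=1):
            x = T.conv2d(x, self.params[f"W_enc_{t}"],
                         self.params[f"b_enc_{t}"], padding=spec.pad)
            x = T.maxpool2d(T.relu(x), *spec.pool)
        return x

    def decode(self, code: Tensor) -> Tensor:
        x = code
        last = len(self.config.decoder)
        for l, spec in enumerate(self.config.decoder, start=1):
            x = T.conv_transpose2d(x, self.params[f"W_dec_{l}"],
                                   self.params[f"b_dec_{l}"],
                                   padding=spec.pad)
            if l < last:
                x = T.relu(x)
        return x

    def head_logits(self, code: Tensor) -> Tensor:
        flat = T.reshape(code, (code.shape[0], self.code_len))
        return T.linear(flat, self.params["W_soft2"], self.params["b_soft2"])

    # -- training ----------------------------------------------------------

    def _cae_params(self):
        return [v for k, v in self.params.items() if not k.endswith("soft2")]

    def _enc_params(self):
        return [v for k, v in self.params.items() if k.startswith(("W_enc", "b_enc"))]

    def _head_params(self):
        return [self.params["W_soft2"], self.params["b_soft2"]]

    def fit_autoencoder(self, P_nchw, epochs=200, lr=1e-3, batch_size=32,
                        seed=0):
        """Pretrain encoder+decoder on reconstruction; per-epoch mean loss."""
        rng = np.random.default_rng(seed)
        opt = T.Adam(self._cae_params(), lr=lr)
        n = P_nchw.shape[0]
        history = []
        for _ in range(epochs):
            order = rng.permutation(n)
            total = 0.0
            for lo in range(0, n, batch_size):
                idx = order[lo:lo + batch_size]
                x = Tensor(P_nchw[idx])
                opt.zero_grad()
                recon = self.decode(self.encode(x))
                diff = T.sub(recon, x)
                loss = T.tsum(T.mul(diff, diff))
                loss.backward()
                opt.step()
                total += loss.data.item()
            history.append(total / n)
        return history

    def fit_classifier(self, P_nchw, labels, epochs_frozen=30,
                       epochs_finetune=30, lr=1e-3, batch_size=32, seed=0):
        """Train the softmax head on frozen codes, then finetune the encoder."""
        labels = np.asarray(labels)
        onehot = np.zeros((len(labels), 2))
        onehot[np.arange(len(labels)), labels] = 1.0
        rng = np.random.default_rng(seed)
        history = []
        for stage, (params, epochs) in enumerate([
                (self._head_params(), epochs_frozen),
                (self._head_params() + self._enc_params(), epochs_finetune)]):
            opt = T.Adam(params, lr=lr)
            frozen_codes = None
            if stage == 0:
                frozen_codes = self.encode(Tensor(P_nchw)).data
            for _ in range(epochs):
                order = rng.permutation(len(labels))
                total = 0.0
                for lo in range(0, len(labels), batch_size):
                    idx = order[lo:lo + batch_size]
                    opt.zero_grad()
                    if stage == 0:
                        code = Tensor(frozen_codes[idx])
                    else:
                        code = self.encode(Tensor(P_nchw[idx]))
                    loss = T.cross_entropy_with_logits(
                        self.head_logits(code), onehot[idx])
                    loss.backward()
                    opt.step()
                    total += loss.data.item()
                history.append(total / len(labels))
        return history

    def scores(self, P_nchw, chunk=256):
        """P(associated) for a batch of embeddings, without gradients."""
        out = np.empty(P_nchw.shape[0])
        for lo in range(0, P_nchw.shape[0], chunk):
            x = Tensor(P_nchw[lo:lo + chunk])
            logit = self.head_logits(self.encode(x)).data
            out[lo:lo + chunk] = softmax_np(logit, axis=-1)[:, 1]
        return out


def cae_encode(P, cae: ConvAutoencoderBranch) -> np.ndarray:
    """Bottleneck feature map F^PA of one embedding (2, N, 3)."""
    x = embedding_to_nchw(np.asarray(P))[None]
    return cae.encode(Tensor(x)).data[0]


def cae_decode(code, cae: ConvAutoencoderBranch) -> np.ndarray:
    """Reconstruction P̂ (2, N, 3) from a bottleneck feature map."""
    out = cae.decode(Tensor(np.asarray(code, dtype=float)[None])).data[0]
    return np.moveaxis(out, 0, -1)
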