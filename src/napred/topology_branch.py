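"""First branch: pairwise neighbor-topology encoding and CNN scoring.

For each heterogeneous network m, the attributes of a node's retained
same-type and cross-type neighbors are mean-aggregated (drug neighbors
contribute rows of the property matrix feeding U^m, disease neighbors rows
of the disease similarity matrix), projected to an N_f-dimensional ReLU
feature per order k, fused across orders by neighbor-scale-level attention
and across the two neighbor types by neighbor-topology-level attention.
The three per-network representations of the drug and of the disease are
concatenated into the 2 x 3N_f pair matrix S, zero-padded by one ring,
passed through a stride-1 CNN (convolution + ReLU + max-pooling), flattened
and scored by a softmax head.

Two parallel code paths exist on purpose: small pure-numpy functions that
state each operation's arithmetic directly, and the trainable
:class:`TopologyBranch` built on the autodiff engine.  A consistency test
holds them together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tensor as T
from ._tensor import Tensor

__all__ = [
    "CNNConfig", "mean_aggregate", "project_fc", "scale_attention",
    "topology_attention", "build_pair_matrix", "cnn_encode", "branch1_score",
    "softmax_np", "TopologyBranch", "aggregate_neighbor_attributes",
]


def softmax_np(x, axis=-1):
    e = np.exp(x - np.max(x, axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class CNNConfig:
    """Convolution/pooling geometry of the pair-matrix encoder.

    Defaults: 16 filters, 2x2 kernels for both convolution and pooling,
    stride 1 throughout, one ring of zero padding before the convolution,
    none before pooling.
    """

    n_conv: int = 16
    conv_kernel: tuple[int, int] = (2, 2)
    pool_kernel: tuple[int, int] = (2, 2)
    pad: int = 1

    def __post_init__(self):
        if min(self.conv_kernel) < 1 or min(self.pool_kernel) < 1:
            raise ValueError("kernel dimensions must be >= 1")

    def out_dims(self, n_f: int):
        """(conv_h, conv_w, pool_h, pool_w, z_len) for a 2 x 3N_f input."""
        h, w = 2 + 2 * self.pad, 3 * n_f + 2 * self.pad
        wl, wh = self.conv_kernel
        if wl > h or wh > w:
            raise ValueError(f"conv kernel {self.conv_kernel} exceeds padded "
                             f"input ({h},{w})")
        ch, cw = h - wl + 1, w - wh + 1
        we, wb = self.pool_kernel
        if we > ch or wb > cw:
            raise ValueError(f"pool kernel {self.pool_kernel} exceeds conv map "
                             f"({ch},{cw})")
        ph, pw = ch - we + 1, cw - wb + 1
        return ch, cw, ph, pw, self.n_conv * ph * pw


# ---------------------------------------------------------------------------
# functional reference operations (pure numpy)
# ---------------------------------------------------------------------------


def mean_aggregate(attr_vectors) -> np.ndarray:
    """Element-wise arithmetic mean of a nonempty list of equal-length vectors."""
    vecs = [np.asarray(v, dtype=float) for v in attr_vectors]
    if not vecs:
        raise ValueError("cannot aggregate an empty neighbor list")
    return np.mean(vecs, axis=0)


def project_fc(h, W, b) -> np.ndarray:
    """ReLU(W h + b) low-dimensional neighbor feature."""
    h = np.asarray(h, dtype=float)
    if not np.isfinite(h).all():
        raise ValueError("non-finite input to fully connected projection")
    return np.maximum(np.asarray(W) @ h + np.asarray(b), 0.0)


def _attention_weights(features, W, b, h):
    scores = np.array([h @ np.tanh(W @ u + b) for u in features])
    return softmax_np(scores)


def scale_attention(features, W, b, h):
    """Softmax-weighted fusion of the order-1..K same-type features."""
    feats = [np.asarray(u, dtype=float) for u in features]
    alpha = _attention_weights(feats, W, b, h)
    return np.tensordot(alpha, np.stack(feats), axes=1), alpha


def topology_attention(u_R, u_D, W, b, h):
    """Two-way softmax fusion of drug-type vs disease-type topologies."""
    alpha = _attention_weights([u_R, u_D], W, b, h)
    return alpha[0] * np.asarray(u_R) + alpha[1] * np.asarray(u_D), alpha


def build_pair_matrix(u_ri, u_dj) -> np.ndarray:
    """Stack the three per-network drug and disease vectors into S (2, 3N_f)."""
    if len(u_ri) != 3 or len(u_dj) != 3:
        raise ValueError("exactly three per-network vectors required per node")
    dims = {np.asarray(v).shape for v in list(u_ri) + list(u_dj)}
    if len(dims) != 1:
        raise ValueError(f"inconsistent vector dimensions: {sorted(dims)}")
    return np.stack([np.concatenate(u_ri), np.concatenate(u_dj)])


def cnn_encode(S, cfg: CNNConfig, W, b) -> np.ndarray:
    """Pad, convolve (ReLU), max-pool and flatten the pair matrix S."""
    S = np.asarray(S, dtype=float)
    out = T.conv2d(Tensor(S[None, None]), Tensor(W), Tensor(b),
                   padding=cfg.pad)
    out = T.maxpool2d(T.relu(out), *cfg.pool_kernel)
    return out.data.reshape(-1)


def branch1_score(z, W, b) -> np.ndarray:
    """Softmax head: probability pair (P(associated), P(not associated))."""
    return softmax_np(np.asarray(W) @ np.asarray(z, dtype=float) + np.asarray(b))


# ---------------------------------------------------------------------------
# neighbor attribute aggregation (fixed inputs to the trainable branch)
# ---------------------------------------------------------------------------


def aggregate_neighbor_attributes(nbr_sets, n_drugs, n_nodes, orders,
                                  drug_attrs, disease_attrs):
    """Mean neighbor-attribute vectors for every node and order.

    Returns ``{("R"|"D", k): array (n_nodes, dim)}``: for each node, the mean
    attribute vector of its drug-type ("R") and disease-type ("D") retained
    neighbors at order k.  Drug-type neighbors contribute rows of
    ``drug_attrs`` (the property matrix feeding this network), disease-type
    neighbors rows of ``disease_attrs`` (the disease similarity matrix).
    An empty neighbor list yields the zero vector.
    """
    out = {}
    for k in orders:
        HR = np.zeros((n_nodes, drug_attrs.shape[1]))
        HD = np.zeros((n_nodes, disease_attrs.shape[1]))
        for node in range(n_nodes):
            ns = nbr_sets[(node, k)]
            if node < n_drugs:
                drug_list, dis_list = ns.same_type, ns.cross_type
            else:
                drug_list, dis_list = ns.cross_type, ns.same_type
            if drug_list:
                HR[node] = drug_attrs[drug_list].mean(axis=0)
            if dis_list:
                HD[node] = disease_attrs[dis_list].mean(axis=0)
        out[("R", k)] = HR
        out[("D", k)] = HD
    return out


# ---------------------------------------------------------------------------
# trainable branch
# ---------------------------------------------------------------------------


def _glorot(rng, shape):
    fan_in = shape[-1]
    fan_out = shape[0] if len(shape) > 1 else shape[-1]
    a = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-a, a, size=shape), requires_grad=True)


class TopologyBranch:
    """Trainable neighbor-topology branch over the three networks.

    Projection weights are separate per network m, neighbor type and order;
    the two attention mechanisms have separate parameters per center node
    type (drug vs disease) but are shared across the three networks.
    """

    def __init__(self, attr_dims, n_f=128, orders=(1, 2), cnn=None, seed=0):
        # attr_dims: {m: (drug_attr_dim, disease_attr_dim)}
        self.attr_dims = dict(attr_dims)
        self.n_f = int(n_f)
        self.orders = tuple(orders)
        self.cnn = cnn or CNNConfig()
        *_, self.z_len = self.cnn.out_dims(self.n_f)
        rng = np.random.default_rng(seed)
        p = {}
        for m, (dim_r, dim_d) in self.attr_dims.items():
            for k in self.orders:
                p[f"W_proj_{m}_R_{k}"] = _glorot(rng, (self.n_f, dim_r))
                p[f"b_proj_{m}_R_{k}"] = Tensor(np.zeros(self.n_f),
                                                requires_grad=True)
                p[f"W_proj_{m}_D_{k}"] = _glorot(rng, (self.n_f, dim_d))
                p[f"b_proj_{m}_D_{k}"] = Tensor(np.zeros(self.n_f),
                                                requires_grad=True)
        for c in ("drug", "disease"):
            for mech in ("scale", "topo"):
                p[f"W_{mech}_{c}"] = _glorot(rng, (self.n_f, self.n_f))
                p[f"b_{mech}_{c}"] = Tensor(np.zeros(self.n_f),
                                            requires_grad=True)
                p[f"h_{mech}_{c}"] = _glorot(rng, (self.n_f,))
        wl, wh = self.cnn.conv_kernel
        p["W_conv"] = _glorot(rng, (self.cnn.n_conv, 1, wl, wh))
        p["b_conv"] = Tensor(np.zeros(self.cnn.n_conv), requires_grad=True)
        p["W_soft1"] = _glorot(rng, (2, self.z_len))
        p["b_soft1"] = Tensor(np.zeros(2), requires_grad=True)
        self.params = p

    def parameters(self):
        return list(self.params.values())

    def _attend(self, feats, mech, center):
        # feats: list over alternatives of Tensor (B, N_f); softmax over them
        p = self.params
        u = T.stack(feats, axis=1)  # (B, n_alt, N_f)
        t = T.tanh(T.linear(u, p[f"W_{mech}_{center}"], p[f"b_{mech}_{center}"]))
        s = T.matmul(t, p[f"h_{mech}_{center}"])       # (B, n_alt)
        alpha = T.softmax(s, axis=-1)                  # (B, n_alt)
        return T.tsum(T.mul(T.reshape(alpha, alpha.shape + (1,)), u), axis=1)

    def _center_repr(self, m, nodes, H, center):
        """Per-network representation u^(m) for an array of center nodes."""
        p = self.params
        fused = {}
        for tau in ("R", "D"):
            per_order = []
            for k in self.orders:
                h = Tensor(H[m][(tau, k)][nodes])
                per_order.append(T.relu(T.linear(
                    h, p[f"W_proj_{m}_{tau}_{k}"], p[f"b_proj_{m}_{tau}_{k}"])))
            fused[tau] = self._attend(per_order, "scale", center)
        return self._attend([fused["R"], fused["D"]], "topo", center)

    def pair_matrix(self, drug_nodes, disease_nodes, H):
        """S tensors (B, 1, 2, 3N_f) for aligned arrays of pair nodes."""
        ms = sorted(self.attr_dims)
        row_r = T.concat([self._center_repr(m, drug_nodes, H, "drug")
                          for m in ms], axis=-1)
        row_d = T.concat([self._center_repr(m, disease_nodes, H, "disease")
                          for m in ms], axis=-1)
        S = T.stack([row_r, row_d], axis=1)            # (B, 2, 3N_f)
        return T.reshape(S, (S.shape[0], 1, 2, 3 * self.n_f))

    def logits(self, drug_nodes, disease_nodes, H):
        p = self.params
        S = self.pair_matrix(drug_nodes, disease_nodes, H)
        z = T.conv2d(S, p["W_conv"], p["b_conv"], padding=self.cnn.pad)
        z = T.maxpool2d(T.relu(z), *self.cnn.pool_kernel)
        z = T.reshape(z, (z.shape[0], self.z_len))
        return T.linear(z, p["W_soft1"], p["b_soft1"])

    def loss(self, drug_nodes, disease_nodes, H, labels):
        """Summed cross-entropy against binary labels (1 = associated)."""
        onehot = np.zeros((len(labels), 2))
        onehot[np.arange(len(labels)), 1 - np.asarray(labels)] = 0.0
        onehot[np.arange(len(labels)), np.asarray(labels)] = 1.0
        return T.cross_entropy_with_logits(
            self.logits(drug_nodes, disease_nodes, H), onehot)

    def scores(self, drug_nodes, disease_nodes, H, chunk=512):
        """P(associated) for aligned node arrays, computed without gradients."""
        out = np.empty(len(drug_nodes))
        for lo in range(0, len(drug_nodes), chunk):
            sl = slice(lo, lo + chunk)
            logit = self.logits(np.asarray(drug_nodes[sl]),
                                np.asarray(disease_nodes[sl]), H).data
            out[sl] = softmax_np(logit, axis=-1)[:, 1]
        return out

    def fit(self, drug_nodes, disease_nodes, H, labels, epochs=60, lr=1e-3,
            batch_size=32, seed=0):
        """Adam minibatch training; returns the per-epoch mean loss."""
        rng = np.random.default_rng(seed)
        opt = T.Adam(self.parameters(), lr=lr)
        n = len(labels)
        drug_nodes = np.asarray(drug_nodes)
        disease_nodes = np.asarray(disease_nodes)
        labels = np.asarray(labels)
        history = []
        for _ in range(epochs):
            order = rng.permutation(n)
            total = 0.0
            for lo in range(0, n, batch_size):
                idx = order[lo:lo + batch_size]
                opt.zero_grad()
                loss = self.loss(drug_nodes[idx], disease_nodes[idx], H,
                                 labels[idx])
                loss.backward()
                opt.step()
                total += loss.data.item()
            history.append(total / n)
        return history
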