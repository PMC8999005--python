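"""Seeded synthetic datasets with planted drug-disease association structure.

The generator emulates the shapes of the real inputs — three binary drug
property matrices, a disease term DAG and a binary association matrix —
while planting a known low-rank signal so that recovery can be measured:

* every drug and disease gets a non-negative latent vector of rank r,
  concentrated on one primary cluster coordinate with a continuous
  intensity plus smaller secondary coordinates (mixed membership);
* each property matrix is partitioned into per-cluster feature blocks; a
  drug carries the blocks of the clusters where its latent coordinate is
  large (its "signature"), then bits are flipped independently with the
  noise rate — so drugs with identical signatures have identical noiseless
  rows, and cosine similarity degrades gracefully with noise;
* the disease DAG is a per-cluster ancestor chain under a shared root; a
  disease attaches at a depth proportional to its primary latent intensity
  (plus a shallow secondary attachment for mixed membership), so semantic
  overlap is graded by the latent geometry;
* associations are Bernoulli with P(A_ij = 1) a logistic function of the
  latent dot product, with the intercept calibrated by bisection to the
  requested density.

Ground-truth latents are returned for audit (e.g. the latent-dot baseline
AUC that certifies the planted signal is present).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network_construction import (AssociationMatrix, DiseaseDAG,
                                   PropertyMatrix, dag_from_edges)

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate_dataset",
           "write_fixture"]

ROOT_TERM = "term_root"


@dataclass
class SyntheticSpec:
    """Reference study conditions for the synthetic fixture."""

    n_drugs: int = 60
    n_diseases: int = 50
    n_features: tuple[int, int, int] = (80, 100, 120)
    rank: int = 3
    density: float = 0.05
    noise: float = 0.1
    seed: int = 42
    # shape constants of the planted signal (held fixed across studies)
    secondary_scale: float = 0.6
    signature_fraction: float = 0.6
    link_gain: float = 25.0
    chain_depth: int = 8
    dag_decay: float = 0.5

    def __post_init__(self):
        if not 0 < self.density < 1:
            raise ValueError(f"density must be in (0,1), got {self.density}")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.n_drugs < 1 or self.n_diseases < 1 or min(self.n_features) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0 <= self.noise <= 1:
            raise ValueError("noise rate must be in [0,1]")
        if self.n_features and min(self.n_features) < self.rank:
            raise ValueError("need at least one feature per latent cluster")


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    properties: list[PropertyMatrix]
    dags: list[DiseaseDAG]
    dag_edges: list[tuple[str, str, str]]
    associations: AssociationMatrix
    drug_latents: np.ndarray
    disease_latents: np.ndarray
    drug_clusters: np.ndarray
    disease_clusters: np.ndarray
    link_probs: np.ndarray = field(repr=False, default=None)


def _latents(rng, n, rank, secondary_scale):
    clusters = rng.integers(rank, size=n)
    X = secondary_scale * rng.uniform(0.0, 1.0, size=(n, rank))
    X[np.arange(n), clusters] = rng.uniform(0.7, 1.0, size=n)
    return X, clusters


def _signature(X, frac):
    return X >= frac * X.max(axis=1, keepdims=True)


def _property_matrix(rng, sig, n_feat, noise, drug_ids, prefix):
    rank = sig.shape[1]
    block = np.array_split(np.arange(n_feat), rank)
    Tm = np.zeros((sig.shape[0], n_feat))
    for k in range(rank):
        Tm[:, block[k]] = sig[:, [k]]
    flips = rng.random(Tm.shape) < noise
    Tm = np.abs(Tm - flips)
    feature_ids = [f"{prefix}_{f:04d}" for f in range(n_feat)]
    return PropertyMatrix(Tm, list(drug_ids), feature_ids)


def _calibrate_intercept(dot, gain, density):
    """Bisection on b so that mean sigmoid(gain*dot + b) == density."""
    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if (1.0 / (1.0 + np.exp(-(gain * dot + mid)))).mean() > density:
            hi = mid
        else:
            lo = mid
    return (lo + hi) / 2


def _chain_edges(cluster, level):
    """Edges of the ancestor chain from attachment level up to the root."""
    edges = []
    for t in range(level, 1, -1):
        edges.append((f"term_c{cluster}_{t}", f"term_c{cluster}_{t - 1}"))
    edges.append((f"term_c{cluster}_1", ROOT_TERM))
    return edges


def _disease_dags(spec, Y, clusters, disease_ids):
    """Per-cluster ancestor chains; attachment depth tracks latent intensity.

    Returns (DiseaseDAG list, flat (disease, child, parent) edge rows).
    """
    L = spec.chain_depth
    dags, rows = [], []
    for j, did in enumerate(disease_ids):
        c = clusters[j]
        intensity = Y[j, c]
        level = 1 + int(round((intensity - 0.7) / 0.3 * (L - 1)))
        level = int(np.clip(level, 1, L))
        edges = [(did, f"term_c{c}_{level}")] + _chain_edges(c, level)
        # shallow secondary attachment for mixed membership
        others = [k for k in range(spec.rank) if k != c]
        if others:
            k2 = max(others, key=lambda k: Y[j, k])
            if Y[j, k2] >= spec.signature_fraction * Y[j, c]:
                edges += [(did, f"term_c{k2}_2")] + _chain_edges(k2, 2)
        edges = list(dict.fromkeys(edges))
        dags.append(dag_from_edges(did, edges, decay=spec.dag_decay))
        rows.extend((did, child, parent) for child, parent in edges)
    return dags, rows


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a complete dataset with planted low-rank association structure."""
    rng = np.random.default_rng(spec.seed)
    drug_ids = [f"drug_{i:04d}" for i in range(spec.n_drugs)]
    disease_ids = [f"disease_{j:04d}" for j in range(spec.n_diseases)]

    X, c_drug = _latents(rng, spec.n_drugs, spec.rank, spec.secondary_scale)
    Y, c_dis = _latents(rng, spec.n_diseases, spec.rank, spec.secondary_scale)

    sig = _signature(X, spec.signature_fraction)
    prefixes = ("chem", "domain", "go")
    properties = [
        _property_matrix(rng, sig, nf, spec.noise, drug_ids, prefix)
        for nf, prefix in zip(spec.n_features, prefixes)
    ]

    dags, dag_edges = _disease_dags(spec, Y, c_dis, disease_ids)

    dot = X @ Y.T
    b = _calibrate_intercept(dot, spec.link_gain, spec.density)
    probs = 1.0 / (1.0 + np.exp(-(spec.link_gain * dot + b)))
    if probs.mean() < spec.density * 0.5 or probs.mean() > spec.density * 2:
        raise ValueError(
            f"target density {spec.density} infeasible for these sizes")
    A = (rng.random(probs.shape) < probs).astype(float)
    associations = AssociationMatrix(A, drug_ids, disease_ids)

    return SyntheticDataset(spec, properties, dags, dag_edges, associations,
                            X, Y, c_drug, c_dis, probs)


def write_fixture(dataset: SyntheticDataset, out_dir) -> dict:
    """Write all inputs as TSV files in the canonical on-disk formats.

    Returns the mapping of logical names to file paths.  The DAG file is an
    edge list (disease_id, term_id, parent_term_id) covering each disease's
    ancestor closure.
    """
    from pathlib import Path

    from . import io_cli

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, pm in zip(("chem", "domain", "go"), dataset.properties):
        paths[name] = out / f"{name}.tsv"
        io_cli.write_matrix(pm.values, pm.drug_ids, pm.feature_ids, paths[name])
    paths["assoc"] = out / "assoc.tsv"
    io_cli.write_matrix(dataset.associations.values,
                        dataset.associations.drug_ids,
                        dataset.associations.disease_ids, paths["assoc"])
    paths["dag"] = out / "dag.tsv"
    io_cli.write_dag_edges(dataset.dag_edges, paths["dag"])
    return paths
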