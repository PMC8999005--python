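"""Construction of the three drug-disease heterogeneous networks.

Drugs are compared by the cosine similarity of binary property profiles
(chemical substructures, target-protein domains, target-protein GO terms),
diseases by semantic similarity over their term DAGs (Wang's
decay-contribution method), and each drug similarity matrix R^m is combined
with the association matrix A and the disease similarity D into one square
network

    U^m = [[R^m, A], [A^T, D]],    m = 1, 2, 3,

over N_r drug nodes followed by N_d disease nodes.  A zero entry means "no
edge"; positive entries are edge weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("napred")

__all__ = [
    "PropertyMatrix", "SimilarityMatrix", "DiseaseDAG", "AssociationMatrix",
    "HeteroNetwork", "cosine_similarity", "wang_disease_similarity",
    "build_hetero_network",
]


def _check_binary(values, name):
    if not np.isin(values, (0, 1)).all():
        bad = np.argwhere(~np.isin(values, (0, 1)))[0]
        raise ValueError(
            f"{name} must be binary; found {values[tuple(bad)]!r} at "
            f"row {bad[0]}, col {bad[1]}"
        )


@dataclass
class PropertyMatrix:
    """Binary drug x feature incidence matrix (one per property source)."""

    values: np.ndarray
    drug_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.drug_ids), len(self.feature_ids)):
            raise ValueError(
                f"property matrix shape {self.values.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.feature_ids)} features"
            )
        _check_binary(self.values, "property matrix")


@dataclass
class AssociationMatrix:
    """Binary drug x disease association matrix A."""

    values: np.ndarray
    drug_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.drug_ids), len(self.disease_ids)):
            raise ValueError(
                f"association matrix shape {self.values.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.disease_ids)} diseases"
            )
        _check_binary(self.values, "association matrix")

    @property
    def n_drugs(self):
        return len(self.drug_ids)

    @property
    def n_diseases(self):
        return len(self.disease_ids)


@dataclass
class SimilarityMatrix:
    """Symmetric similarity matrix with entries in [0, 1]."""

    values: np.ndarray
    node_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.node_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"similarity matrix shape {self.values.shape} does not match "
                f"{n} node ids"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("similarity matrix contains non-finite entries")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix is not symmetric")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-9:
            raise ValueError("similarity values must lie in [0, 1]")


@dataclass
class DiseaseDAG:
    """Ancestor terms of one disease with layer depths (own term at depth 0).

    ``depths`` maps term id -> smallest number of parent steps from the
    disease's own term.  ``decay`` is the per-layer semantic decay factor
    Delta in (0, 1); a term at depth L contributes decay**L.
    """

    disease_id: str
    depths: dict[str, int]
    decay: float = 0.5

    def __post_init__(self):
        if not 0 < self.decay < 1:
            raise ValueError(f"decay factor must be in (0,1), got {self.decay}")
        if not self.depths:
            raise ValueError(f"disease {self.disease_id!r} has an empty DAG")
        if self.depths.get(self.disease_id) != 0:
            raise ValueError(
                f"disease {self.disease_id!r} must contain its own term at depth 0"
            )

    def contributions(self):
        """Semantic contribution decay**depth of every term."""
        return {t: self.decay ** L for t, L in self.depths.items()}

    def semantic_value(self):
        return sum(self.contributions().values())


@dataclass
class HeteroNetwork:
    """Square drug+disease network U^m; drugs first, then diseases."""

    values: np.ndarray
    n_drugs: int
    n_diseases: int
    m: int
    drug_ids: list[str] = field(default_factory=list)
    disease_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        n = self.n_drugs + self.n_diseases
        if self.values.shape != (n, n):
            raise ValueError(
                f"hetero network shape {self.values.shape}, expected ({n},{n})"
            )

    @property
    def drug_block(self):
        return self.values[: self.n_drugs, : self.n_drugs]

    @property
    def assoc_block(self):
        return self.values[: self.n_drugs, self.n_drugs:]

    @property
    def disease_block(self):
        return self.values[self.n_drugs:, self.n_drugs:]


def cosine_similarity(T: PropertyMatrix) -> SimilarityMatrix:
    """Pairwise cosine similarity of the binary property rows.

    A drug whose property row is all zeros has no defined angle; by
    convention it gets similarity 0 to every other drug and 1 to itself,
    and a warning naming the drug is logged.
    """
    X = T.values
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    for drug in np.asarray(T.drug_ids, dtype=object)[zero]:
        logger.warning("drug %s has an all-zero property row; "
                       "similarity set to 0 (self-similarity 1)", drug)
    safe = np.where(zero, 1.0, norms)
    S = (X @ X.T) / np.outer(safe, safe)
    S[zero, :] = 0.0
    S[:, zero] = 0.0
    np.fill_diagonal(S, 1.0)
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    return SimilarityMatrix(S, list(T.drug_ids))


def wang_disease_similarity(dags, disease_ids=None) -> SimilarityMatrix:
    """Semantic similarity between diseases from their term DAGs.

    Each term t in the DAG of disease d contributes S_d(t) = Delta**depth(t);
    the semantic value is DV(d) = sum_t S_d(t) and

        sim(d1, d2) = sum_{t shared} (S_d1(t) + S_d2(t)) / (DV(d1) + DV(d2)).
    """
    by_id = {dag.disease_id: dag for dag in dags}
    if disease_ids is None:
        disease_ids = list(by_id)
    missing = [d for d in disease_ids if d not in by_id]
    if missing:
        raise ValueError(f"diseases missing from DAG collection: {missing}")
    contribs = {d: by_id[d].contributions() for d in disease_ids}
    dv = {d: sum(c.values()) for d, c in contribs.items()}
    n = len(disease_ids)
    D = np.eye(n)
    for a in range(n):
        ca = contribs[disease_ids[a]]
        for b in range(a + 1, n):
            cb = contribs[disease_ids[b]]
            shared = ca.keys() & cb.keys()
            if shared:
                num = sum(ca[t] + cb[t] for t in shared)
                D[a, b] = D[b, a] = num / (dv[disease_ids[a]] + dv[disease_ids[b]])
    return SimilarityMatrix(np.clip(D, 0.0, 1.0), list(disease_ids))


def dag_from_edges(disease_id: str, edges, decay: float = 0.5) -> DiseaseDAG:
    """Build a DiseaseDAG from (child_term, parent_term) edges.

    Depth of a term is the smallest number of parent steps from the
    disease's own term (breadth-first over the edge relation); the disease
    term itself sits at depth 0 even if no edges are given.
    """
    parents: dict[str, set[str]] = {}
    for child, parent in edges:
        parents.setdefault(child, set()).add(parent)
    depths = {disease_id: 0}
    frontier = [disease_id]
    while frontier:
        nxt = []
        for term in frontier:
            for parent in parents.get(term, ()):
                if parent not in depths:
                    depths[parent] = depths[term] + 1
                    nxt.append(parent)
        frontier = nxt
    return DiseaseDAG(disease_id, depths, decay=decay)


def build_hetero_network(R: SimilarityMatrix, A: AssociationMatrix,
                         D: SimilarityMatrix, m: int) -> HeteroNetwork:
    """Assemble U^m = [[R, A], [A^T, D]] over drug-then-disease nodes."""
    n_r, n_d = A.n_drugs, A.n_diseases
    if R.values.shape != (n_r, n_r):
        raise ValueError(
            f"drug similarity shape {R.values.shape} incompatible with "
            f"{n_r} drugs (expected ({n_r},{n_r}))"
        )
    if D.values.shape != (n_d, n_d):
        raise ValueError(
            f"disease similarity shape {D.values.shape} incompatible with "
            f"{n_d} diseases (expected ({n_d},{n_d}))"
        )
    U = np.block([[R.values, A.values], [A.values.T, D.values]])
    return HeteroNetwork(U, n_r, n_d, m,
                         drug_ids=list(A.drug_ids),
                         disease_ids=list(A.disease_ids))
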