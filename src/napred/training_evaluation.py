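"""Training, cross-validation and evaluation of the two-branch predictor.

Protocol: known associations are positives; unknown pairs are negatives.
Positives are partitioned into k folds; each fold trains on the remaining
positives plus an equal-ratio seeded sample of unknown pairs and is tested
on the held-out positives plus every unknown pair not used as a training
negative.  Both branches are trained separately with cross-entropy losses
and their P(associated) outputs combined as

    Score = lambda * Score_NT + (1 - lambda) * Score_PA.

Metrics follow the per-drug protocol: AUC and AUPR are computed per drug
within each fold over that drug's test diseases, averaged over folds, then
averaged over drugs; top-k recall pools each fold's ranked test pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .attribute_branch import ConvAutoencoderBranch, embedding_to_nchw
from .metapath_neighbors import all_neighbor_sets
from .network_construction import (AssociationMatrix, SimilarityMatrix,
                                   build_hetero_network, cosine_similarity)
from .topology_branch import TopologyBranch, aggregate_neighbor_attributes

logger = logging.getLogger("napred")

__all__ = [
    "TrainConfig", "FoldSplit", "cross_entropy_loss", "combine_scores",
    "make_folds", "compute_metrics", "evaluate_per_drug",
    "rank_novel_candidates", "NAPredPipeline", "permute_associations",
]


@dataclass
class TrainConfig:
    """Hyperparameters of a cross-validated run (see RunConfig for I/O)."""

    lambda_: float = 0.5
    learning_rate: float = 1e-3
    epochs: int = 100
    cae_epochs: int = 100
    head_epochs_frozen: int = 30
    head_epochs_finetune: int = 30
    batch_size: int = 32
    neg_ratio: float = 1.0
    folds: int = 5
    seed: int = 0
    n_f: int = 128
    n_k: dict = field(default_factory=lambda: {1: 10, 2: 20})
    orders: tuple = (1, 2)
    top_k: tuple = (30, 60, 90, 120, 150)

    def __post_init__(self):
        if not 0.0 <= self.lambda_ <= 1.0:
            raise ValueError(f"lambda must be in [0,1], got {self.lambda_}")
        if self.folds < 2:
            raise ValueError("fold count must be >= 2")

    @classmethod
    def reference_evaluation(cls, seed=1) -> "TrainConfig":
        """Scaled-down study configuration used for the reference fixture.

        Feature width and epoch counts are reduced relative to the library
        defaults so that a full five-fold run completes in minutes on one
        CPU; on the 60-drug/50-disease fixture the reduced capacity is
        already past the accuracy plateau.
        """
        return cls(n_f=32, epochs=20, cae_epochs=20, head_epochs_frozen=10,
                   head_epochs_finetune=10, folds=5, seed=seed)


@dataclass
class FoldSplit:
    """Index lists of (drug, disease) pairs for one cross-validation fold."""

    train_pos: list
    train_neg: list
    test_pos: list
    test_neg: list


def cross_entropy_loss(scores, labels) -> float:
    """-sum_i log p_i(true class) over probability pairs (p0, p1)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    p = scores[np.arange(len(labels)), labels]
    if (p <= 0).any():
        logger.warning("clamping %d zero probabilities in cross-entropy",
                       int((p <= 0).sum()))
        p = np.clip(p, 1e-12, None)
    return float(-np.log(p).sum())


def combine_scores(score_nt, score_pa, lam) -> np.ndarray:
    """Affine combination lambda*Score_NT + (1-lambda)*Score_PA."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0,1], got {lam}")
    return lam * np.asarray(score_nt) + (1.0 - lam) * np.asarray(score_pa)


def make_folds(A: AssociationMatrix, cfg: TrainConfig) -> list[FoldSplit]:
    """Seeded per-positive partition with sampled training negatives."""
    rng = np.random.default_rng(cfg.seed)
    pos = [tuple(p) for p in np.argwhere(A.values == 1)]
    if len(pos) < cfg.folds:
        raise ValueError(f"{len(pos)} positives cannot fill {cfg.folds} folds")
    neg = [tuple(p) for p in np.argwhere(A.values == 0)]
    order = rng.permutation(len(pos))
    chunks = np.array_split(order, cfg.folds)
    folds = []
    for chunk in chunks:
        held = set(int(i) for i in chunk)
        test_pos = [pos[i] for i in chunk]
        train_pos = [pos[i] for i in order if int(i) not in held]
        n_neg = min(int(round(cfg.neg_ratio * len(train_pos))), len(neg))
        pick = rng.choice(len(neg), size=n_neg, replace=False)
        train_neg = [neg[i] for i in pick]
        test_neg = [neg[i] for i in range(len(neg)) if i not in set(pick)]
        folds.append(FoldSplit(train_pos, train_neg, test_pos, test_neg))
    return folds


def compute_metrics(scores, labels, top_k=()) -> dict:
    """AUC (trapezoidal ROC), AUPR (PR step curve), curves and top-k recall."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("metrics require at least one positive and one "
                         "negative label")
    fpr, tpr, _ = skm.roc_curve(labels, scores)
    prec, rec, _ = skm.precision_recall_curve(labels, scores)
    out = {
        "auc": float(skm.roc_auc_score(labels, scores)),
        "aupr": float(skm.average_precision_score(labels, scores)),
        "roc_curve": (fpr, tpr),
        "pr_curve": (prec, rec),
    }
    if top_k:
        order = np.lexsort((np.arange(len(scores)), -scores))
        ranked = labels[order]
        out["top_k_recall"] = {
            int(k): float(ranked[:k].sum() / n_pos) for k in top_k
        }
    return out


def evaluate_per_drug(fold_frames, top_k=()) -> dict:
    """Per-drug fold-mean AUC/AUPR and their global (over-drug) means.

    ``fold_frames`` are per-fold tables with columns drug, disease, label,
    score.  A drug without a test positive (or negative) in a fold is
    skipped for that fold; a drug skipped in every fold is excluded from
    the global mean and logged.
    """
    per_drug: dict = {}
    for frame in fold_frames:
        for drug, grp in frame.groupby("drug", sort=True):
            labels = grp["label"].to_numpy()
            if labels.min() == labels.max():
                logger.debug("drug %s has a single test class in this fold; "
                             "skipped", drug)
                continue
            m = compute_metrics(grp["score"].to_numpy(), labels)
            per_drug.setdefault(drug, []).append((m["auc"], m["aupr"]))
    if not per_drug:
        raise ValueError("no drug had both classes in any fold")
    rows = {d: (float(np.mean([a for a, _ in v])),
                float(np.mean([p for _, p in v])))
            for d, v in sorted(per_drug.items())}
    result = {
        "per_drug": {d: {"auc": a, "aupr": p} for d, (a, p) in rows.items()},
        "mean_auc": float(np.mean([a for a, _ in rows.values()])),
        "mean_aupr": float(np.mean([p for _, p in rows.values()])),
    }
    if top_k:
        recalls = {int(k): [] for k in top_k}
        for frame in fold_frames:
            m = compute_metrics(frame["score"].to_numpy(),
                                frame["label"].to_numpy(), top_k=top_k)
            for k, v in m["top_k_recall"].items():
                recalls[k].append(v)
        result["top_k_recall"] = {k: float(np.mean(v))
                                  for k, v in recalls.items()}
    return result


def rank_novel_candidates(score_frame, A: AssociationMatrix, top_n=30):
    """Per drug, unknown diseases sorted by combined score (desc, index asc)."""
    known = A.values[score_frame["drug"].to_numpy(),
                     score_frame["disease"].to_numpy()]
    frame = score_frame[known == 0]
    out = []
    for drug, grp in frame.groupby("drug", sort=True):
        grp = grp.sort_values(["score", "disease"],
                              ascending=[False, True], kind="mergesort")
        for rank, (_, row) in enumerate(grp.head(top_n).iterrows(), start=1):
            out.append((A.drug_ids[int(drug)], rank,
                        A.disease_ids[int(row["disease"])],
                        float(row["score"])))
    return pd.DataFrame(out, columns=["drug_id", "rank", "disease_id", "score"])


def permute_associations(A: AssociationMatrix, seed=0) -> AssociationMatrix:
    """Destroy the signal by shuffling all association entries (same count)."""
    rng = np.random.default_rng(seed)
    flat = A.values.flatten()
    rng.shuffle(flat)
    return AssociationMatrix(flat.reshape(A.values.shape),
                             list(A.drug_ids), list(A.disease_ids))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


class NAPredPipeline:
    """End-to-end two-branch predictor over the three heterogeneous networks.

    Networks are rebuilt per fold from training associations only, and the
    pair's own association entries are masked out of its attribute
    embedding, so the label of a scored pair never appears in its inputs.
    """

    def __init__(self, properties, disease_sim: SimilarityMatrix,
                 A: AssociationMatrix, cfg: TrainConfig):
        if len(properties) != 3:
            raise ValueError("exactly three drug property matrices required")
        self.properties = list(properties)
        self.disease_sim = disease_sim
        self.A = A
        self.cfg = cfg
        self.drug_sims = [cosine_similarity(T) for T in self.properties]
        self.n_r, self.n_d = A.n_drugs, A.n_diseases

    # -- per-fold machinery ------------------------------------------------

    def _networks(self, A_train):
        return [build_hetero_network(R, A_train, self.disease_sim, m)
                for m, R in enumerate(self.drug_sims, start=1)]

    def _aggregated(self, nets):
        cfg = self.cfg
        H = {}
        for m, U in enumerate(nets, start=1):
            nbrs = all_neighbor_sets(U, cfg.orders, cfg.n_k)
            H[m] = aggregate_neighbor_attributes(
                nbrs, self.n_r, self.n_r + self.n_d, cfg.orders,
                self.properties[m - 1].values, self.disease_sim.values)
        return H

    def _embeddings(self, nets, pairs):
        """Masked NCHW attribute embeddings for a list of (i, j) pairs."""
        stack = np.stack([U.values for U in nets])  # (3, N, N)
        idx = np.asarray(pairs, dtype=int)
        drug_rows = stack[:, idx[:, 0], :]                 # (3, B, N)
        dis_rows = stack[:, self.n_r + idx[:, 1], :]       # (3, B, N)
        P = np.stack([drug_rows, dis_rows], axis=2)        # (3, B, 2, N)
        P = np.moveaxis(P, 1, 0)                           # (B, 3, 2, N)
        b = np.arange(len(idx))
        P[b, :, 0, self.n_r + idx[:, 1]] = 0.0
        P[b, :, 1, idx[:, 0]] = 0.0
        return P

    def _train_fold(self, fold: FoldSplit, seeds):
        cfg = self.cfg
        A_train = np.array(self.A.values)
        for i, j in fold.test_pos:
            A_train[i, j] = 0.0
        A_train = AssociationMatrix(A_train, list(self.A.drug_ids),
                                    list(self.A.disease_ids))
        nets = self._networks(A_train)
        H = self._aggregated(nets)

        pairs = fold.train_pos + fold.train_neg
        labels = np.array([1] * len(fold.train_pos) +
                          [0] * len(fold.train_neg))
        idx = np.asarray(pairs, dtype=int)
        drug_nodes = idx[:, 0]
        disease_nodes = self.n_r + idx[:, 1]

        attr_dims = {m: (self.properties[m - 1].values.shape[1], self.n_d)
                     for m in (1, 2, 3)}
        branch1 = TopologyBranch(attr_dims, n_f=cfg.n_f, orders=cfg.orders,
                                 seed=seeds[0])
        branch1.fit(drug_nodes, disease_nodes, H, labels,
                    epochs=cfg.epochs, lr=cfg.learning_rate,
                    batch_size=cfg.batch_size, seed=seeds[1])

        P_train = self._embeddings(nets, pairs)
        branch2 = ConvAutoencoderBranch((3, 2, self.n_r + self.n_d),
                                        seed=seeds[2])
        branch2.fit_autoencoder(P_train, epochs=cfg.cae_epochs,
                                lr=cfg.learning_rate,
                                batch_size=cfg.batch_size, seed=seeds[3])
        branch2.fit_classifier(P_train, labels,
                               epochs_frozen=cfg.head_epochs_frozen,
                               epochs_finetune=cfg.head_epochs_finetune,
                               lr=cfg.learning_rate,
                               batch_size=cfg.batch_size, seed=seeds[4])
        return nets, H, branch1, branch2

    def _score_pairs(self, nets, H, branch1, branch2, pairs):
        idx = np.asarray(pairs, dtype=int)
        s_nt = branch1.scores(idx[:, 0], self.n_r + idx[:, 1], H)
        s_pa = branch2.scores(self._embeddings(nets, pairs))
        return s_nt, s_pa

    # -- public API --------------------------------------------------------

    def run_cv(self) -> dict:
        """Full k-fold cross-validation; returns fold tables and metrics."""
        cfg = self.cfg
        folds = make_folds(self.A, cfg)
        child = np.random.SeedSequence(cfg.seed).spawn(len(folds))
        frames = []
        for f, fold in enumerate(folds):
            seeds = [int(s) for s in child[f].generate_state(5) % (2 ** 31)]
            logger.info("fold %d/%d: %d train pos, %d train neg, %d test pos",
                        f + 1, len(folds), len(fold.train_pos),
                        len(fold.train_neg), len(fold.test_pos))
            nets, H, b1, b2 = self._train_fold(fold, seeds)
            pairs = fold.test_pos + fold.test_neg
            labels = np.array([1] * len(fold.test_pos) +
                              [0] * len(fold.test_neg))
            s_nt, s_pa = self._score_pairs(nets, H, b1, b2, pairs)
            idx = np.asarray(pairs, dtype=int)
            frames.append(pd.DataFrame({
                "fold": f, "drug": idx[:, 0], "disease": idx[:, 1],
                "label": labels, "score_nt": s_nt, "score_pa": s_pa,
                "score": combine_scores(s_nt, s_pa, cfg.lambda_),
            }))
        summary = evaluate_per_drug(frames, top_k=cfg.top_k)
        return {"folds": frames, "summary": summary}

    def fit_full(self):
        """Train on all known associations (for novel-candidate ranking)."""
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)
        pos = [tuple(p) for p in np.argwhere(self.A.values == 1)]
        neg = [tuple(p) for p in np.argwhere(self.A.values == 0)]
        n_neg = min(int(round(cfg.neg_ratio * len(pos))), len(neg))
        pick = rng.choice(len(neg), size=n_neg, replace=False)
        fold = FoldSplit(pos, [neg[i] for i in pick], [], [])
        seeds = [int(s) for s in
                 np.random.SeedSequence(cfg.seed).generate_state(5) % (2 ** 31)]
        self._fitted = self._train_fold(fold, seeds)
        return self

    def predict_novel(self, top_n=30):
        """Ranked unknown-association candidates per drug, trained on full A."""
        if not hasattr(self, "_fitted"):
            self.fit_full()
        nets, H, b1, b2 = self._fitted
        unknown = [tuple(p) for p in np.argwhere(self.A.values == 0)]
        s_nt, s_pa = self._score_pairs(nets, H, b1, b2, unknown)
        idx = np.asarray(unknown, dtype=int)
        frame = pd.DataFrame({
            "drug": idx[:, 0], "disease": idx[:, 1],
            "score": combine_scores(s_nt, s_pa, self.cfg.lambda_),
        })
        return rank_novel_candidates(frame, self.A, top_n=top_n)
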