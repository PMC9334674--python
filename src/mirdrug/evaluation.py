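"""Leakage-safe cross-validation, metrics, and case-study ranking protocols.

Positive pairs are the known interactions; an equal number of negatives is
drawn once, uniformly, from the unconfirmed pairs.  Five-fold CV partitions
positives and negatives separately (stratified); for each fold the
topological embedding is re-trained on the fold's training edges only, so
test interactions never inform any feature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score, roc_curve

from mirdrug.bine import BineConfig, train_bine
from mirdrug.features import AttributeFeatureTable, featurize_tables
from mirdrug.graph import BipartiteGraph, load_bipartite_edges, restrict_to_training
from mirdrug.predictor import (
    DnnConfig,
    Model,
    assemble_pairs,
    predict_pairs,
    stack_features,
    train_classifier,
)

Pair = tuple[int, int]


@dataclass
class MdiDataset:
    """An interaction graph together with attribute features for its nodes."""

    graph: BipartiteGraph
    attributes: AttributeFeatureTable

    @classmethod
    def from_paths(cls, edges_path, fasta_path, drug_table_path) -> "MdiDataset":
        return cls(
            graph=load_bipartite_edges(edges_path),
            attributes=featurize_tables(fasta_path, drug_table_path),
        )

    def pair_ids(self, pairs) -> list[tuple[str, str]]:
        return [(self.graph.drug_ids[i], self.graph.mirna_ids[j]) for i, j in pairs]


def sample_negative_pairs(positives, drugs, mirnas, n: int, rng) -> set[Pair]:
    """``n`` distinct pairs drawn uniformly from the unconfirmed universe.

    ``drugs``/``mirnas`` may be id lists or node counts; pairs are index
    tuples disjoint from ``positives``.
    """
    nd = drugs if isinstance(drugs, int) else len(drugs)
    nm = mirnas if isinstance(mirnas, int) else len(mirnas)
    positives = set(positives)
    capacity = nd * nm - len(positives)
    if capacity < n:
        raise ValueError(f"only {capacity} unconfirmed pairs exist; cannot draw {n}")
    negatives: set[Pair] = set()
    if n > capacity // 2:  # dense case: enumerate and choose exactly
        universe = [(i, j) for i in range(nd) for j in range(nm) if (i, j) not in positives]
        idx = rng.choice(len(universe), size=n, replace=False)
        return {universe[k] for k in idx}
    while len(negatives) < n:
        i = int(rng.integers(nd))
        j = int(rng.integers(nm))
        if (i, j) not in positives and (i, j) not in negatives:
            negatives.add((i, j))
    return negatives


@dataclass
class FoldedDataset:
    """Positives + sampled negatives partitioned into k disjoint test folds."""

    positives: list[Pair]
    negatives: list[Pair]
    folds: list[dict]  # each: {"test_pos": [...], "test_neg": [...]}

    @property
    def k(self) -> int:
        return len(self.folds)

    def train_edges(self, fold: int) -> set[Pair]:
        """Training-graph edge set: all positives minus this fold's test positives."""
        return set(self.positives) - set(self.folds[fold]["test_pos"])

    def train_samples(self, fold: int) -> tuple[list[Pair], np.ndarray]:
        test = set(self.folds[fold]["test_pos"]) | set(self.folds[fold]["test_neg"])
        pairs = [p for p in self.positives if p not in test] + [
            p for p in self.negatives if p not in test
        ]
        labels = np.array(
            [1] * sum(p not in test for p in self.positives)
            + [0] * sum(p not in test for p in self.negatives)
        )
        return pairs, labels

    def test_samples(self, fold: int) -> tuple[list[Pair], np.ndarray]:
        pos = self.folds[fold]["test_pos"]
        neg = self.folds[fold]["test_neg"]
        return list(pos) + list(neg), np.array([1] * len(pos) + [0] * len(neg))


def make_folds(positives, negatives, k: int = 5, rng=None) -> FoldedDataset:
    """Stratified k-way partition: positives and negatives are split separately."""
    if k < 2:
        raise ValueError("k must be >= 2")
    positives = list(positives)
    negatives = list(negatives)
    if len(positives) < k:
        raise ValueError(f"need at least k={k} positives")
    if set(positives) & set(negatives):
        raise ValueError("positives and negatives overlap")
    rng = np.random.default_rng() if rng is None else rng
    pos_order = rng.permutation(len(positives))
    neg_order = rng.permutation(len(negatives))
    folds = []
    for pos_idx, neg_idx in zip(np.array_split(pos_order, k), np.array_split(neg_order, k)):
        folds.append(
            {
                "test_pos": [positives[i] for i in pos_idx],
                "test_neg": [negatives[i] for i in neg_idx],
            }
        )
    return FoldedDataset(positives, negatives, folds)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(bool)
        y_pred = np.asarray(y_pred).astype(bool)
        return cls(
            tp=int(np.sum(y_true & y_pred)),
            tn=int(np.sum(~y_true & ~y_pred)),
            fp=int(np.sum(~y_true & y_pred)),
            fn=int(np.sum(y_true & ~y_pred)),
        )


def confusion_metrics(c: ConfusionCounts) -> dict:
    """Accuracy, sensitivity, specificity, precision and MCC.

    Metrics whose denominator is zero are reported as ``None``.
    """
    total = c.tp + c.tn + c.fp + c.fn

    def ratio(num, den):
        return num / den if den > 0 else None

    mcc_den = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    mcc = (c.tp * c.tn - c.fp * c.fn) / np.sqrt(mcc_den) if mcc_den > 0 else None
    return {
        "acc": ratio(c.tp + c.tn, total),
        "sen": ratio(c.tp, c.tp + c.fn),
        "spec": ratio(c.tn, c.tn + c.fp),
        "prec": ratio(c.tp, c.tp + c.fp),
        "mcc": mcc,
    }


def roc_pr_curves(scores, labels):
    """ROC-AUC (trapezoidal) and AUPR (step-wise integral) with curve points."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(labels, scores))
    aupr = float(average_precision_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores)
    prec, rec, _ = precision_recall_curve(labels, scores)
    return auc, aupr, {"roc": (fpr, tpr), "pr": (rec, prec)}


def write_curves_tsv(scores, labels, roc_path, pr_path) -> None:
    """Write ROC and PR curve points as TSV for external plotting."""
    _, _, curves = roc_pr_curves(scores, labels)
    fpr, tpr = curves["roc"]
    with open(roc_path, "w") as fh:
        fh.write("fpr\ttpr\n")
        for x, y in zip(fpr, tpr):
            fh.write(f"{x:.6f}\t{y:.6f}\n")
    rec, prec = curves["pr"]
    with open(pr_path, "w") as fh:
        fh.write("recall\tprecision\n")
        for x, y in zip(rec, prec):
            fh.write(f"{x:.6f}\t{y:.6f}\n")


@dataclass
class MetricReport:
    """Per-fold metrics with mean and population standard deviation."""

    per_fold: list[dict]
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mean:
            keys = [k for k in self.per_fold[0] if self.per_fold[0][k] is not None]
            for k in keys:
                vals = np.array([f[k] for f in self.per_fold], dtype=float)
                self.mean[k] = float(vals.mean())
                self.sd[k] = float(vals.std())  # population SD over folds

    def to_json(self, path=None) -> str:
        payload = {"per_fold": self.per_fold, "mean": self.mean, "sd": self.sd}
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary_table(self) -> str:
        keys = list(self.mean)
        lines = ["metric\t" + "\t".join(f"fold{i+1}" for i in range(len(self.per_fold))) + "\tmean\tsd"]
        for k in keys:
            vals = "\t".join(f"{f[k]:.4f}" if f[k] is not None else "NA" for f in self.per_fold)
            lines.append(f"{k}\t{vals}\t{self.mean[k]:.4f}\t{self.sd[k]:.4f}")
        return "\n".join(lines)


def fold_metrics(y_true, scores) -> dict:
    auc, aupr, _ = roc_pr_curves(scores, y_true)
    counts = ConfusionCounts.from_predictions(y_true, np.asarray(scores) > 0.5)
    out = confusion_metrics(counts)
    out.update(auc=auc, aupr=aupr)
    return out


# ---------------------------------------------------------------------------
# cross-validation protocol
# ---------------------------------------------------------------------------

def _assemble(dataset: MdiDataset, pairs, emb, mode, labels=None):
    g = dataset.graph
    ids = dataset.pair_ids(pairs)
    d_index = {d: i for i, d in enumerate(g.drug_ids)}
    m_index = {m: j for j, m in enumerate(g.mirna_ids)}
    return assemble_pairs(ids, dataset.attributes, emb, mode, d_index, m_index, labels=labels)


def cv_fold_scores(
    dataset: MdiDataset,
    folded: FoldedDataset,
    bine_cfg: BineConfig,
    dnn_cfg: DnnConfig,
    modes=("both",),
    permute_labels: bool = False,
    seed: int = 0,
) -> dict[str, list[tuple[np.ndarray, np.ndarray]]]:
    """Per-fold (y_true, scores) for each feature mode, sharing one embedding
    per fold.

    With ``permute_labels`` the sample labels are permuted (a null control):
    features are computed exactly as in the real protocol, so test AUC is
    expected at chance level.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, list] = {m: [] for m in modes}
    for fold in range(folded.k):
        g_train = restrict_to_training(dataset.graph, folded.train_edges(fold))
        emb = train_bine(g_train, bine_cfg.with_(seed=int(rng.integers(2**31 - 1))))
        train_pairs, y_train = folded.train_samples(fold)
        test_pairs, y_test = folded.test_samples(fold)
        if permute_labels:
            y_train = y_train[rng.permutation(len(y_train))]
            y_test = y_test[rng.permutation(len(y_test))]
        for mode in modes:
            tr = _assemble(dataset, train_pairs, emb, mode, labels=y_train)
            te = _assemble(dataset, test_pairs, emb, mode)
            model = train_classifier(tr, dnn_cfg.with_(feature_mode=mode, seed=int(rng.integers(2**31 - 1))))
            scores, _ = predict_pairs(model, te)
            out[mode].append((y_test, scores))
    return out


def run_cv(
    dataset: MdiDataset,
    bine_cfg: BineConfig | None = None,
    dnn_cfg: DnnConfig | None = None,
    k: int = 5,
    seed: int = 0,
    permute_labels: bool = False,
) -> MetricReport:
    """Full leakage-safe k-fold cross-validation of the interaction predictor.

    Per fold, topological features are re-learned on the fold's training
    edges only, the classifier is trained on the training pairs, and the
    held-out pairs are scored.
    """
    bine_cfg = bine_cfg or BineConfig()
    dnn_cfg = dnn_cfg or DnnConfig()
    rng = np.random.default_rng(seed)
    positives = sorted(dataset.graph.edges)
    negatives = sorted(
        sample_negative_pairs(positives, dataset.graph.n_drugs, dataset.graph.n_mirnas, len(positives), rng)
    )
    folded = make_folds(positives, negatives, k=k, rng=rng)
    scores = cv_fold_scores(
        dataset, folded, bine_cfg, dnn_cfg,
        modes=(dnn_cfg.feature_mode,), permute_labels=permute_labels,
        seed=int(rng.integers(2**31 - 1)),
    )[dnn_cfg.feature_mode]
    return MetricReport(per_fold=[fold_metrics(y, s) for y, s in scores])


# ---------------------------------------------------------------------------
# case-study protocols
# ---------------------------------------------------------------------------

def rank_candidates(model: Model, candidates, top_n: int) -> list[tuple[str, str, float]]:
    """Candidates sorted by predicted score, descending; ties broken by
    (drug_id, mirna_id)."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    scores, _ = predict_pairs(model, candidates)
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-scores[i], candidates[i].drug_id, candidates[i].mirna_id),
    )
    return [(candidates[i].drug_id, candidates[i].mirna_id, float(scores[i])) for i in order[:top_n]]


def leave_one_drug_out(
    dataset: MdiDataset,
    drug_id: str,
    bine_cfg: BineConfig | None = None,
    dnn_cfg: DnnConfig | None = None,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """Rank all miRNAs for a drug whose interactions are withheld.

    Every edge touching ``drug_id`` is removed before embedding and classifier
    training, so the drug is a cold-start node represented by attributes only
    (zero topology block).  Returns (mirna_id, score) for every miRNA, best
    first.
    """
    bine_cfg = bine_cfg or BineConfig()
    dnn_cfg = dnn_cfg or DnnConfig()
    g = dataset.graph
    a = g.drug_index(drug_id)
    rng = np.random.default_rng(seed)

    train_pos = sorted(p for p in g.edges if p[0] != a)
    if not train_pos:
        raise ValueError("no training edges remain after removing the drug")
    excluded = set(g.edges) | {(a, j) for j in range(g.n_mirnas)}
    capacity = g.n_drugs * g.n_mirnas - len(excluded)
    train_neg = sorted(
        sample_negative_pairs(excluded, g.n_drugs, g.n_mirnas, min(len(train_pos), capacity), rng)
    )
    g_train = restrict_to_training(g, train_pos)
    emb = train_bine(g_train, bine_cfg.with_(seed=int(rng.integers(2**31 - 1))))

    y = np.array([1] * len(train_pos) + [0] * len(train_neg))
    tr = _assemble(dataset, train_pos + train_neg, emb, dnn_cfg.feature_mode, labels=y)
    model = train_classifier(tr, dnn_cfg.with_(seed=int(rng.integers(2**31 - 1))))

    cand_pairs = [(a, j) for j in range(g.n_mirnas)]
    cand = _assemble(dataset, cand_pairs, emb, dnn_cfg.feature_mode)
    ranked = rank_candidates(model, cand, top_n=len(cand))
    return [(m, s) for _, m, s in ranked]
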