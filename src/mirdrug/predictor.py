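"""Pair-feature assembly and the dense neural-network interaction classifier.

A candidate (drug, miRNA) pair is represented by the fixed concatenation

    [drug MACCS (166) ⊕ drug topology (dim) ⊕ miRNA 3-mer (64) ⊕ miRNA topology (dim)]

and scored by a single-hidden-layer dense network (256 rectified units by
default) with a sigmoid output, trained with binary cross-entropy under the
Adam optimizer.  ``feature_mode`` masks out blocks for ablation studies;
cold-start nodes (absent from the training graph) carry zero topology
blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import joblib
import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from mirdrug.bine import NodeEmbeddingTable
from mirdrug.features import AttributeFeatureTable, N_MACCS_KEYS

FEATURE_MODES = ("both", "attribute_only", "topology_only")


@dataclass
class DnnConfig:
    hidden_units: int = 256
    activation: str = "relu"
    dropout_rate: float = 0.0
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 50
    seed: int = 0
    feature_mode: str = "both"
    # weight decay: the default single hidden layer has ~10^5 parameters
    # while typical fold training sets have ~10^3 pairs, so substantial L2
    # is needed for the network to generalize rather than memorize folds
    # (scikit-learn scales the penalty by 1/n_samples)
    l2: float = 1.0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.feature_mode not in FEATURE_MODES:
            raise ValueError(f"feature_mode must be one of {FEATURE_MODES}")
        if self.dropout_rate != 0.0:
            raise ValueError("dropout is not supported by this backend; use 0.0")

    def with_(self, **kw) -> "DnnConfig":
        return replace(self, **kw)


@dataclass
class PairFeature:
    drug_id: str
    mirna_id: str
    vector: np.ndarray
    label: int | None = None
    cold_drug: bool = False
    cold_mirna: bool = False


def feature_length(mode: str, dim: int, kmer_dim: int = 64) -> int:
    if mode == "both":
        return N_MACCS_KEYS + kmer_dim + 2 * dim
    if mode == "attribute_only":
        return N_MACCS_KEYS + kmer_dim
    if mode == "topology_only":
        return 2 * dim
    raise ValueError(f"unknown feature_mode {mode!r}")


def mode_columns(mode: str, dim: int, kmer_dim: int = 64) -> np.ndarray:
    """Column indices of a ``both``-mode feature matrix belonging to ``mode``.

    Layout: [MACCS (166) | drug topo (dim) | k-mer (kmer_dim) | miRNA topo (dim)].
    """
    maccs = np.arange(N_MACCS_KEYS)
    d_topo = N_MACCS_KEYS + np.arange(dim)
    kmer = N_MACCS_KEYS + dim + np.arange(kmer_dim)
    m_topo = N_MACCS_KEYS + dim + kmer_dim + np.arange(dim)
    if mode == "both":
        return np.concatenate([maccs, d_topo, kmer, m_topo])
    if mode == "attribute_only":
        return np.concatenate([maccs, kmer])
    if mode == "topology_only":
        return np.concatenate([d_topo, m_topo])
    raise ValueError(f"unknown feature_mode {mode!r}")


def assemble_pairs(
    pairs,
    attr_table: AttributeFeatureTable,
    emb_table: NodeEmbeddingTable | None,
    mode: str = "both",
    drug_index: dict[str, int] | None = None,
    mirna_index: dict[str, int] | None = None,
    labels=None,
) -> list[PairFeature]:
    """Build PairFeature vectors for (drug_id, mirna_id) pairs.

    Attribute vectors must exist for every endpoint (they are computable from
    SMILES/sequence alone); topology vectors are looked up in ``emb_table``
    via the index maps and zero-filled for nodes without one (cold start).
    """
    if mode not in FEATURE_MODES:
        raise ValueError(f"unknown feature_mode {mode!r}")
    need_topo = mode in ("both", "topology_only")
    if need_topo and emb_table is None:
        raise ValueError(f"feature_mode {mode!r} requires an embedding table")
    dim = emb_table.dim if emb_table is not None else 0
    out: list[PairFeature] = []
    for idx, (d, m) in enumerate(pairs):
        blocks = []
        cold_d = cold_m = False
        if mode in ("both", "attribute_only"):
            if d not in attr_table.drug:
                raise KeyError(f"no attribute vector for drug {d!r}")
            if m not in attr_table.mirna:
                raise KeyError(f"no attribute vector for miRNA {m!r}")
        if need_topo:
            di = drug_index.get(d) if drug_index else None
            mi = mirna_index.get(m) if mirna_index else None
            d_topo = emb_table.drug_vecs[di] if di is not None else np.zeros(dim)
            m_topo = emb_table.mirna_vecs[mi] if mi is not None else np.zeros(dim)
            cold_d = di is None or not d_topo.any()
            cold_m = mi is None or not m_topo.any()
        if mode == "both":
            blocks = [attr_table.drug[d], d_topo, attr_table.mirna[m], m_topo]
        elif mode == "attribute_only":
            blocks = [attr_table.drug[d], attr_table.mirna[m]]
        else:
            blocks = [d_topo, m_topo]
        vec = np.concatenate([np.asarray(b, dtype=float) for b in blocks])
        label = None if labels is None else int(labels[idx])
        out.append(PairFeature(d, m, vec, label, cold_d, cold_m))
    return out


def stack_features(pair_features: list[PairFeature]) -> tuple[np.ndarray, np.ndarray | None]:
    X = np.vstack([p.vector for p in pair_features])
    if all(p.label is not None for p in pair_features):
        y = np.array([p.label for p in pair_features], dtype=int)
    else:
        y = None
    return X, y


class Model:
    """Trained interaction classifier (thin wrapper around an MLP)."""

    def __init__(self, mlp: MLPClassifier, feature_mode: str, n_features: int):
        self.mlp = mlp
        self.feature_mode = feature_mode
        self.n_features = n_features

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "Model":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a model checkpoint")
        return model


def train_classifier(train_pairs: list[PairFeature], cfg: DnnConfig) -> Model:
    """Fit the dense network on labeled pair features.

    Architecture: input → dense(hidden_units, activation) → dense(1, sigmoid),
    trained with binary cross-entropy (log-loss) and Adam.
    """
    X, y = stack_features(train_pairs)
    if y is None:
        raise ValueError("all training pairs must carry labels")
    return fit_matrix(X, y, cfg)


def fit_matrix(X: np.ndarray, y: np.ndarray, cfg: DnnConfig) -> Model:
    """Fit the classifier directly on a feature matrix and label vector."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    mlp = MLPClassifier(
        hidden_layer_sizes=(cfg.hidden_units,),
        activation=cfg.activation,
        solver="adam",
        alpha=cfg.l2,
        learning_rate_init=cfg.learning_rate,
        batch_size=min(cfg.batch_size, X.shape[0]),
        max_iter=cfg.epochs,
        shuffle=True,
        random_state=cfg.seed,
        n_iter_no_change=max(10, cfg.epochs),
        tol=1e-6,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        mlp.fit(X, y)
    return Model(mlp, cfg.feature_mode, X.shape[1])


def predict_pairs(model: Model, pairs: list[PairFeature]) -> tuple[np.ndarray, np.ndarray]:
    """Interaction scores P_ij ∈ [0, 1] and labels by the strict rule P_ij > 0.5."""
    X, _ = stack_features(pairs)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature length {X.shape[1]} does not match model input {model.n_features}"
        )
    scores = model.mlp.predict_proba(X)[:, list(model.mlp.classes_).index(1)]
    return scores, (scores > 0.5).astype(int)


def write_predictions_tsv(path, pairs: list[PairFeature], scores, labels) -> None:
    with open(path, "w") as fh:
        fh.write("drug_id\tmirna_id\tscore\tlabel\n")
        for p, s, lab in zip(pairs, scores, labels):
            fh.write(f"{p.drug_id}\t{p.mirna_id}\t{s:.6f}\t{int(lab)}\n")
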