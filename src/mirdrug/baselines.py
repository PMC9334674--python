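"""Classical comparison methods: collaborative filtering, truncated-SVD
matrix factorization, and two-way resource diffusion.

All baselines are pure functions of the (training) adjacency and similarity
matrices; none learns state, so fixed inputs give bitwise-stable outputs.
Similarities are computed only from training-fold information (interaction
profiles of the training adjacency, or attribute vectors), never from test
edges, to avoid label leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

CF_VARIANTS = ("drug", "mirna", "neighbor")


@dataclass
class ScoreMatrix:
    """|D|x|M| matrix of predicted interaction scores plus a provenance tag."""

    matrix: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("score matrix contains non-finite entries")


def pcc_similarity(features_a, features_b) -> float:
    """Pearson correlation of two equal-length feature vectors.

    Zero-variance inputs are defined as similarity 0 (with a warning), so
    constant fingerprints do not poison the similarity matrix.
    """
    a = np.asarray(features_a, dtype=float)
    b = np.asarray(features_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("features must be equal-length 1-D vectors")
    if a.size < 2:
        raise ValueError("features must have length >= 2")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        warnings.warn("zero-variance feature vector; PCC defined as 0", stacklevel=2)
        return 0.0
    return float(((a - a.mean()) @ (b - b.mean())) / (a.size * sa * sb))


def similarity_matrix(feature_rows: np.ndarray) -> np.ndarray:
    """Pairwise PCC matrix over row vectors (zero-variance rows get 0)."""
    X = np.asarray(feature_rows, dtype=float)
    sd = X.std(axis=1)
    ok = sd > 0
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.outer(sd, sd) * X.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        P = (Xc @ Xc.T) / denom
    P[~ok, :] = 0.0
    P[:, ~ok] = 0.0
    np.fill_diagonal(P, np.where(ok, 1.0, 0.0))
    return P


def cf_scores(adjacency: np.ndarray, sim_drug: np.ndarray | None, sim_mirna: np.ndarray | None, variant: str = "neighbor") -> ScoreMatrix:
    """Collaborative-filtering score matrices.

    drug variant: M' = (P_drug · M) / n_d; miRNA variant: M' = (M · P_miRNAᵀ) / n_m;
    neighbor variant: elementwise mean of both.
    """
    M = np.asarray(adjacency, dtype=float)
    nd, nm = M.shape
    if variant not in CF_VARIANTS:
        raise ValueError(f"variant must be one of {CF_VARIANTS}")
    if variant in ("drug", "neighbor"):
        P = np.asarray(sim_drug, dtype=float)
        if P.shape != (nd, nd):
            raise ValueError(f"drug similarity shape {P.shape} != ({nd},{nd})")
        drug_scores = (P @ M) / nd
        if variant == "drug":
            return ScoreMatrix(drug_scores, "drug_cf")
    if variant in ("mirna", "neighbor"):
        P = np.asarray(sim_mirna, dtype=float)
        if P.shape != (nm, nm):
            raise ValueError(f"miRNA similarity shape {P.shape} != ({nm},{nm})")
        mirna_scores = (M @ P.T) / nm
        if variant == "mirna":
            return ScoreMatrix(mirna_scores, "mirna_cf")
    return ScoreMatrix((drug_scores + mirna_scores) / 2.0, "neighbor_cf")


def svd_mf_scores(adjacency: np.ndarray, rank: int = 8) -> ScoreMatrix:
    """Rank-k truncated-SVD reconstruction U_k Σ_k V_kᵀ as the score matrix."""
    M = np.asarray(adjacency, dtype=float)
    if not (1 <= rank <= min(M.shape)):
        raise ValueError(f"rank must lie in [1, {min(M.shape)}], got {rank}")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    recon = (U[:, :rank] * s[:rank]) @ Vt[:rank]
    return ScoreMatrix(recon, f"svd_mf_k{rank}")


def two_way_diffusion(adjacency: np.ndarray, weighted_adjacency: np.ndarray | None = None) -> ScoreMatrix:
    """Two-way resource diffusion over the weighted bipartite network.

    Drug-side resource vectors: R_D[a, l] = Σ_m A^w[a, m]·A[l, m] / Σ_i A^w[i, m]
    (columns with zero A^w sum are skipped); miRNA-side resource vectors:
    R_M[b, j] = Σ_l A^w[l, b]·A[l, j] / Σ_i A^w[l, i] (zero-sum rows skipped).
    The pair score combines both diffusion directions:
    S = (R_D · A + A · R_Mᵀ) / 2.

    ``weighted_adjacency`` (A^w) defaults to the adjacency itself; a
    similarity-weighted adjacency may be supplied instead.
    """
    A = np.asarray(adjacency, dtype=float)
    Aw = A if weighted_adjacency is None else np.asarray(weighted_adjacency, dtype=float)
    if Aw.shape != A.shape:
        raise ValueError("weighted adjacency shape mismatch")
    if (Aw < 0).any():
        raise ValueError("weighted adjacency must be nonnegative")

    col = Aw.sum(axis=0)
    col_safe = np.where(col > 0, col, 1.0)
    R_drug = (Aw / col_safe) @ A.T  # [a, l]

    row = Aw.sum(axis=1)
    row_safe = np.where(row > 0, row, 1.0)
    R_mirna = (Aw / row_safe[:, None]).T @ A  # [b, j]

    S = (R_drug @ A + A @ R_mirna.T) / 2.0
    return ScoreMatrix(S, "two_way_diffusion")


def export_scores_tsv(path, scores: ScoreMatrix, drug_ids, mirna_ids) -> None:
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(mirna_ids) + "\n")
        for d, row in zip(drug_ids, scores.matrix):
            fh.write(d + "\t" + "\t".join(format(v, ".6g") for v in row) + "\n")
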