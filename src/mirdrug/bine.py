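"""Bipartite network embedding (BiNE-style) for the drug-miRNA graph.

The embedding jointly optimizes three terms by stochastic gradient ascent:

* an *explicit* term reconstructing the observed edge distribution
  P(i,j) = w_ij / Σw through sigmoid inner products σ(d⃗ᵢᵀm⃗ⱼ), minimizing the
  KL divergence between the two (weighted by γ);
* two *implicit* skip-gram terms (weighted α for drugs, β for miRNAs) over
  corpora of truncated random walks on the co-HITS homogeneous projections,
  with negative sampling approximating the softmax denominator.

Walk starts are biased by HITS centrality ("richer get richer"): high-
centrality nodes seed more walks, and each step stops with a fixed
probability so sequences have variable length.

The per-sample update rules are exposed as :func:`sga_step_explicit` /
:func:`sga_step_implicit`; :func:`train_bine` runs the same updates through a
numba-compiled inner loop for the default negative-sampling strategy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from mirdrug.graph import BipartiteGraph, HomogeneousWeights, cohits_projection

_SIG_CLIP = 35.0


def sigmoid(x):
    """Numerically clipped logistic function."""
    return 1.0 / (1.0 + np.exp(-np.clip(x, -_SIG_CLIP, _SIG_CLIP)))


@dataclass
class BineConfig:
    """Hyper-parameters of the bipartite embedding.

    Structural defaults follow the original BiNE settings (skip-gram window
    5, 4 negatives per positive, at most 32 walks per node, per-step stop
    probability 0.15, ``dim`` 64).  The gradient scale (objective weights
    ``gamma`` = 1.0 explicit, ``alpha`` = ``beta`` = 0.1 implicit, learning
    rate 0.025, 50 epochs, at least 16 walks per node) is calibrated for
    interaction networks of the 10^2-10^3 node scale this package targets:
    on such graphs each node contributes few SGA samples per epoch, so the
    per-sample step must be correspondingly larger for the joint objective
    to converge.
    """

    dim: int = 64
    alpha: float = 0.1
    beta: float = 0.1
    gamma: float = 1.0
    lr: float = 0.025
    window: int = 5
    ns: int = 4
    max_walks_per_node: int = 32
    min_walks_per_node: int = 16
    stop_prob: float = 0.15
    epochs: int = 50
    seed: int = 0
    negative_strategy: str = "unigram"  # "unigram" | "uniform" | "lsh"
    lsh_planes: int = 4

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if min(self.alpha, self.beta, self.gamma) <= 0:
            raise ValueError("alpha, beta, gamma must be positive")
        if not (0 < self.stop_prob <= 1):
            raise ValueError("stop_prob must lie in (0, 1]")
        if self.min_walks_per_node > self.max_walks_per_node:
            raise ValueError("min_walks_per_node must not exceed max_walks_per_node")
        if self.window < 1 or self.ns < 1:
            raise ValueError("window and ns must be >= 1")
        if self.negative_strategy not in ("unigram", "uniform", "lsh"):
            raise ValueError(f"unknown negative_strategy {self.negative_strategy!r}")

    def with_(self, **kw) -> "BineConfig":
        return replace(self, **kw)


@dataclass
class NodeEmbeddingTable:
    """Embedding (d⃗, m⃗) and context (θ⃗, ϑ⃗) vectors for both node sides."""

    drug_vecs: np.ndarray
    mirna_vecs: np.ndarray
    drug_ctx: np.ndarray
    mirna_ctx: np.ndarray

    def __post_init__(self) -> None:
        for name in ("drug_vecs", "mirna_vecs", "drug_ctx", "mirna_ctx"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")

    @property
    def dim(self) -> int:
        return self.drug_vecs.shape[1]

    @classmethod
    def init_random(cls, n_drugs: int, n_mirnas: int, dim: int, rng) -> "NodeEmbeddingTable":
        # entries ~ N(0, 1/dim): rows start near unit norm with inner
        # products ~ N(0, 1/dim), i.e. sigmoid scores near 0.5
        sd = 1.0 / np.sqrt(dim)
        return cls(
            drug_vecs=rng.normal(0.0, sd, (n_drugs, dim)),
            mirna_vecs=rng.normal(0.0, sd, (n_mirnas, dim)),
            drug_ctx=rng.normal(0.0, sd, (n_drugs, dim)),
            mirna_ctx=rng.normal(0.0, sd, (n_mirnas, dim)),
        )

    def save(self, drug_path, mirna_path, drug_ids, mirna_ids) -> None:
        save_word2vec(drug_path, drug_ids, self.drug_vecs)
        save_word2vec(mirna_path, mirna_ids, self.mirna_vecs)

    @classmethod
    def from_word2vec(cls, drug_path, mirna_path, drug_ids, mirna_ids) -> "NodeEmbeddingTable":
        """Load externally computed embeddings (context vectors are zeroed).

        This is the pluggable-embedder path: any method that writes the
        word2vec text format (DeepWalk, LINE, node2vec, ...) can supply the
        topological features.
        """
        d_ids, dv = load_word2vec(drug_path)
        m_ids, mv = load_word2vec(mirna_path)
        dmap = {k: i for i, k in enumerate(d_ids)}
        mmap = {k: i for i, k in enumerate(m_ids)}
        try:
            dv = dv[[dmap[k] for k in drug_ids]]
            mv = mv[[mmap[k] for k in mirna_ids]]
        except KeyError as exc:
            raise KeyError(f"embedding file is missing node {exc}") from None
        return cls(dv, mv, np.zeros_like(dv), np.zeros_like(mv))


@dataclass
class WalkCorpus:
    """Bag of variable-length same-type node index sequences."""

    side: str
    sequences: list[list[int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequences)


# ---------------------------------------------------------------------------
# explicit relation (observed edges)
# ---------------------------------------------------------------------------

def explicit_joint_probability(g: BipartiteGraph, i: int, j: int) -> float:
    """Empirical edge probability P(i,j) = w_ij / Σ_{edges} w."""
    if (i, j) not in g.edges:
        raise KeyError(f"({i},{j}) is not an edge")
    return g.edges[(i, j)] / g.total_weight()


def local_proximity(d_vec: np.ndarray, m_vec: np.ndarray) -> float:
    """Reconstructed edge probability P̂(i,j) = σ(d⃗ᵢᵀm⃗ⱼ)."""
    d_vec = np.asarray(d_vec, dtype=float)
    m_vec = np.asarray(m_vec, dtype=float)
    if d_vec.shape != m_vec.shape:
        raise ValueError("embedding vectors differ in length")
    return float(sigmoid(d_vec @ m_vec))


def explicit_loss(g: BipartiteGraph, emb: NodeEmbeddingTable) -> float:
    """KL divergence Σ P(i,j) log(P(i,j)/P̂(i,j)) over observed edges."""
    total = g.total_weight()
    loss = 0.0
    for (i, j), w in g.edges.items():
        p = w / total
        phat = local_proximity(emb.drug_vecs[i], emb.mirna_vecs[j])
        loss += p * np.log(p / phat)
    return float(loss)


# ---------------------------------------------------------------------------
# walk corpus on the homogeneous projections
# ---------------------------------------------------------------------------

def hits_centrality(h: HomogeneousWeights, tol: float = 1e-12, max_iter: int = 1000) -> np.ndarray:
    """HITS authority scores on a symmetric homogeneous network.

    On a symmetric matrix hubs and authorities coincide with the dominant
    eigenvector; computed by power iteration with L1 normalization.  An
    all-zero matrix yields uniform scores (with a warning).
    """
    mat = h.dense()
    n = mat.shape[0]
    if not np.allclose(mat, mat.T):
        raise ValueError("homogeneous weight matrix must be symmetric")
    if not mat.any():
        warnings.warn("all-zero homogeneous network; uniform centrality", stacklevel=2)
        return np.full(n, 1.0 / n)
    # power iteration on M + sI: same dominant eigenvector for symmetric
    # nonnegative M, but immune to the period-2 oscillation of bipartite-like
    # structures where +/-lambda_max eigenvalue pairs occur
    shift = float(mat.max())
    shifted = mat + shift * np.eye(n)
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        y = shifted @ x
        s = np.abs(y).sum()
        if s == 0:  # pragma: no cover - symmetric nonneg matrix cannot reach this
            break
        y /= s
        if np.abs(y - x).sum() < tol:
            x = y
            break
        x = y
    x = np.clip(x, 0.0, None)
    return x / x.sum()


def _walk_counts(centrality: np.ndarray, cfg: BineConfig) -> np.ndarray:
    raw = np.rint(cfg.max_walks_per_node * centrality).astype(int)
    return np.clip(raw, cfg.min_walks_per_node, cfg.max_walks_per_node)


def generate_walks(h: HomogeneousWeights, centrality: np.ndarray, cfg: BineConfig, rng) -> WalkCorpus:
    """Biased truncated random walks on one homogeneous projection.

    Each node v seeds ``clamp(round(maxT * centrality(v)), minT, maxT)``
    walks.  A walk repeatedly continues with probability ``1 - stop_prob``,
    stepping to a neighbor drawn proportionally to off-diagonal edge weight;
    it ends on the stop event or at a dead end, so lengths are variable and
    at least 1.
    """
    mat = h.dense().astype(float).copy()
    np.fill_diagonal(mat, 0.0)  # self-transitions carry no context
    n = mat.shape[0]
    neighbors: list[np.ndarray] = []
    cdfs: list[np.ndarray] = []
    for v in range(n):
        nbr = np.flatnonzero(mat[v] > 0)
        neighbors.append(nbr)
        if nbr.size:
            c = np.cumsum(mat[v, nbr])
            cdfs.append(c / c[-1])
        else:
            cdfs.append(np.empty(0))

    counts = _walk_counts(np.asarray(centrality, dtype=float), cfg)
    sequences: list[list[int]] = []
    cont = 1.0 - cfg.stop_prob
    for v in range(n):
        for _ in range(counts[v]):
            seq = [v]
            cur = v
            while rng.random() < cont:
                nbr = neighbors[cur]
                if nbr.size == 0:
                    break
                cur = int(nbr[np.searchsorted(cdfs[cur], rng.random(), side="right")])
                seq.append(cur)
            sequences.append(seq)
    return WalkCorpus(side=h.side, sequences=sequences)


def context_pairs(corpus: WalkCorpus, window: int) -> tuple[np.ndarray, np.ndarray]:
    """All (center, context) index pairs within ``window`` positions."""
    if window < 1:
        raise ValueError("window must be >= 1")
    centers: list[int] = []
    contexts: list[int] = []
    for seq in corpus.sequences:
        L = len(seq)
        for t in range(L):
            lo = max(0, t - window)
            hi = min(L, t + window + 1)
            for u in range(lo, hi):
                if u != t:
                    centers.append(seq[t])
                    contexts.append(seq[u])
    return np.asarray(centers, dtype=np.int64), np.asarray(contexts, dtype=np.int64)


# ---------------------------------------------------------------------------
# SGA update rules
# ---------------------------------------------------------------------------

def sga_step_explicit(emb: NodeEmbeddingTable, g: BipartiteGraph, i: int, j: int, cfg: BineConfig) -> NodeEmbeddingTable:
    """One ascent step on the explicit term γ·w_ij·log σ(d⃗ᵢᵀm⃗ⱼ), in place.

    Both rows are updated with the gradient evaluated at the pre-update
    vectors.
    """
    if (i, j) not in g.edges:
        raise KeyError(f"({i},{j}) is not an edge")
    w = g.edges[(i, j)]
    d = emb.drug_vecs[i].copy()
    m = emb.mirna_vecs[j]
    coef = cfg.lr * cfg.gamma * w * (1.0 - sigmoid(d @ m))
    emb.drug_vecs[i] += coef * m
    emb.mirna_vecs[j] += coef * d
    return emb


def sga_step_implicit(emb: NodeEmbeddingTable, center: int, contexts_with_negatives, side: str, cfg: BineConfig) -> NodeEmbeddingTable:
    """One skip-gram-with-negative-sampling ascent step for ``center``.

    ``contexts_with_negatives`` is an iterable of ``(node, is_positive)``.
    The center embedding accumulates Σ_z λ·κ·(I(z) − σ(v⃗ᵀθ⃗_z))·θ⃗_z and each
    context row θ⃗_z moves by λ·κ·(I(z) − σ(v⃗ᵀθ⃗_z))·v⃗, with κ = α on the
    drug side and β on the miRNA side, all gradients evaluated at the
    pre-update center vector.
    """
    if side == "drug":
        vecs, ctx, kappa = emb.drug_vecs, emb.drug_ctx, cfg.alpha
    elif side == "mirna":
        vecs, ctx, kappa = emb.mirna_vecs, emb.mirna_ctx, cfg.beta
    else:
        raise ValueError(f"side must be 'drug' or 'mirna', got {side!r}")
    v_old = vecs[center].copy()
    delta = np.zeros_like(v_old)
    for z, is_positive in contexts_with_negatives:
        indicator = 1.0 if is_positive else 0.0
        gcoef = cfg.lr * kappa * (indicator - sigmoid(v_old @ ctx[z]))
        delta += gcoef * ctx[z]
        ctx[z] += gcoef * v_old
    vecs[center] += delta
    return emb


def sample_negatives(center: int, positives, side_nodes, ns: int, rng, strategy: str = "uniform", degrees=None, embeddings=None, lsh_planes: int = 4) -> list[int]:
    """Draw ``ns`` negative nodes (with replacement) excluding center/positives.

    Strategies: ``uniform``; ``unigram`` (probability ∝ degree^0.75, standard
    skip-gram practice); ``lsh`` (random-hyperplane hash of current
    embeddings, drawing uniformly from buckets other than the center's).
    """
    side_nodes = np.asarray(side_nodes)
    excluded = set(positives) | {center}
    pool = np.array([v for v in side_nodes if v not in excluded])
    if pool.size == 0:
        warnings.warn("empty negative-sampling pool; returning no negatives", stacklevel=2)
        return []
    if strategy == "uniform":
        p = None
    elif strategy == "unigram":
        if degrees is None:
            raise ValueError("unigram strategy requires degrees")
        degrees = np.asarray(degrees, dtype=float)
        w = degrees[pool] ** 0.75
        p = w / w.sum() if w.sum() > 0 else None
    elif strategy == "lsh":
        if embeddings is None:
            raise ValueError("lsh strategy requires embeddings")
        planes = rng.standard_normal((embeddings.shape[1], lsh_planes))
        codes = (np.asarray(embeddings) @ planes > 0) @ (1 << np.arange(lsh_planes))
        other = pool[codes[pool] != codes[center]]
        if other.size:
            pool = other
        p = None
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    idx = rng.choice(len(pool), size=ns, replace=True, p=p)
    return [int(pool[i]) for i in idx]


# ---------------------------------------------------------------------------
# numba fast path for the training loop
# ---------------------------------------------------------------------------

@njit(cache=False)
def _explicit_epoch(dvec, mvec, ei, ej, ew, order, lr_gamma):
    dim = dvec.shape[1]
    for t in range(order.shape[0]):
        e = order[t]
        i = ei[e]
        j = ej[e]
        x = 0.0
        for k in range(dim):
            x += dvec[i, k] * mvec[j, k]
        if x > _SIG_CLIP:
            x = _SIG_CLIP
        elif x < -_SIG_CLIP:
            x = -_SIG_CLIP
        coef = lr_gamma * ew[e] * (1.0 - 1.0 / (1.0 + np.exp(-x)))
        for k in range(dim):
            d_old = dvec[i, k]
            dvec[i, k] += coef * mvec[j, k]
            mvec[j, k] += coef * d_old


@njit(cache=False)
def _implicit_epoch(vecs, ctx, centers, contexts, order, cdf, ns, lr_kappa, seed):
    np.random.seed(seed)
    dim = vecs.shape[1]
    v_old = np.empty(dim)
    delta = np.empty(dim)
    for t in range(order.shape[0]):
        p = order[t]
        c = centers[p]
        zpos = contexts[p]
        for k in range(dim):
            v_old[k] = vecs[c, k]
            delta[k] = 0.0
        for r in range(ns + 1):
            if r == 0:
                z = zpos
                indicator = 1.0
            else:
                z = c
                for _ in range(64):  # rejection: exclude center and positive
                    u = np.random.random()
                    z = np.searchsorted(cdf, u, side="right")
                    if z != c and z != zpos:
                        break
                if z == c or z == zpos:
                    continue
                indicator = 0.0
            x = 0.0
            for k in range(dim):
                x += v_old[k] * ctx[z, k]
            if x > _SIG_CLIP:
                x = _SIG_CLIP
            elif x < -_SIG_CLIP:
                x = -_SIG_CLIP
            coef = lr_kappa * (indicator - 1.0 / (1.0 + np.exp(-x)))
            for k in range(dim):
                delta[k] += coef * ctx[z, k]
                ctx[z, k] += coef * v_old[k]
        for k in range(dim):
            vecs[c, k] += delta[k]


def _negative_cdf(h: HomogeneousWeights, strategy: str) -> np.ndarray:
    mat = h.dense().copy()
    np.fill_diagonal(mat, 0.0)
    deg = mat.sum(axis=1)
    if strategy == "unigram" and deg.sum() > 0:
        w = deg ** 0.75
    else:
        w = np.ones(h.n_nodes)
    cdf = np.cumsum(w / w.sum())
    cdf[-1] = 1.0
    return cdf


# ---------------------------------------------------------------------------
# joint training
# ---------------------------------------------------------------------------

def train_bine(g: BipartiteGraph, cfg: BineConfig) -> NodeEmbeddingTable:
    """Train the joint explicit + implicit objective on a bipartite graph.

    Per epoch: one ascent pass over shuffled edges (explicit term), then one
    pass over the shuffled context pairs of each homogeneous corpus (implicit
    terms with negative sampling).  Walk corpora are generated once from the
    HITS-biased generator.  Fully deterministic under ``cfg.seed``.  Nodes
    isolated in ``g`` (cold start) are zeroed in the returned table, since no
    topological information exists for them.
    """
    if g.n_edges == 0:
        raise ValueError("cannot embed a graph with no edges")
    rng = np.random.default_rng(cfg.seed)
    emb = NodeEmbeddingTable.init_random(g.n_drugs, g.n_mirnas, cfg.dim, rng)

    proj = {side: cohits_projection(g, side) for side in ("drug", "mirna")}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cent = {side: hits_centrality(proj[side]) for side in ("drug", "mirna")}
    corpora = {side: generate_walks(proj[side], cent[side], cfg, rng) for side in ("drug", "mirna")}
    pairs = {side: context_pairs(corpora[side], cfg.window) for side in ("drug", "mirna")}

    edge_items = sorted(g.edges.items())
    ei = np.array([i for (i, _), _ in edge_items], dtype=np.int64)
    ej = np.array([j for (_, j), _ in edge_items], dtype=np.int64)
    ew = np.array([w for _, w in edge_items], dtype=float)

    if cfg.negative_strategy in ("unigram", "uniform"):
        cdf = {side: _negative_cdf(proj[side], cfg.negative_strategy) for side in ("drug", "mirna")}
        for _ in range(cfg.epochs):
            order = rng.permutation(len(ei))
            _explicit_epoch(emb.drug_vecs, emb.mirna_vecs, ei, ej, ew, order, cfg.lr * cfg.gamma)
            for side, vecs, ctx, kappa in (
                ("drug", emb.drug_vecs, emb.drug_ctx, cfg.alpha),
                ("mirna", emb.mirna_vecs, emb.mirna_ctx, cfg.beta),
            ):
                centers, contexts = pairs[side]
                if centers.size == 0:
                    continue
                order = rng.permutation(centers.size)
                seed = int(rng.integers(0, 2**31 - 1))
                _implicit_epoch(vecs, ctx, centers, contexts, order, cdf[side], cfg.ns, cfg.lr * kappa, seed)
    else:  # LSH bucketing: reference per-sample loop
        _train_python(g, emb, pairs, proj, cfg, rng, ei, ej)

    for i in np.flatnonzero(g.drug_degrees() == 0):
        emb.drug_vecs[i] = 0.0
        emb.drug_ctx[i] = 0.0
    for j in np.flatnonzero(g.mirna_degrees() == 0):
        emb.mirna_vecs[j] = 0.0
        emb.mirna_ctx[j] = 0.0
    return emb


def _train_python(g, emb, pairs, proj, cfg, rng, ei, ej):
    """Pure-Python epoch loop built from the single-step update functions."""
    side_nodes = {"drug": np.arange(g.n_drugs), "mirna": np.arange(g.n_mirnas)}
    degs = {}
    for side in ("drug", "mirna"):
        mat = proj[side].dense().copy()
        np.fill_diagonal(mat, 0.0)
        degs[side] = mat.sum(axis=1)
    for _ in range(cfg.epochs):
        for e in rng.permutation(len(ei)):
            sga_step_explicit(emb, g, int(ei[e]), int(ej[e]), cfg)
        for side in ("drug", "mirna"):
            centers, contexts = pairs[side]
            if centers.size == 0:
                continue
            embeddings = emb.drug_vecs if side == "drug" else emb.mirna_vecs
            for p in rng.permutation(centers.size):
                c, z = int(centers[p]), int(contexts[p])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    negs = sample_negatives(
                        c, [z], side_nodes[side], cfg.ns, rng,
                        strategy=cfg.negative_strategy, degrees=degs[side],
                        embeddings=embeddings, lsh_planes=cfg.lsh_planes,
                    )
                sga_step_implicit(emb, c, [(z, True)] + [(n, False) for n in negs], side, cfg)


# ---------------------------------------------------------------------------
# word2vec text format I/O
# ---------------------------------------------------------------------------

def save_word2vec(path, ids, matrix) -> None:
    """Write embeddings in word2vec text format: ``count dim`` header, then
    ``node_id v1 ... vdim`` rows."""
    matrix = np.asarray(matrix)
    if len(ids) != matrix.shape[0]:
        raise ValueError("id list and matrix row count differ")
    with open(path, "w") as fh:
        fh.write(f"{matrix.shape[0]} {matrix.shape[1]}\n")
        for nid, row in zip(ids, matrix):
            fh.write(str(nid) + " " + " ".join(repr(float(v)) for v in row) + "\n")


def load_word2vec(path) -> tuple[list[str], np.ndarray]:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header")
        n, dim = int(header[0]), int(header[1])
        ids: list[str] = []
        mat = np.zeros((n, dim))
        for r in range(n):
            parts = fh.readline().split()
            if len(parts) != dim + 1:
                raise ValueError(f"{path}: malformed row {r + 2}")
            ids.append(parts[0])
            mat[r] = [float(v) for v in parts[1:]]
    return ids, mat
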