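"""Numerical self-checks: SGA update rules vs finite-difference gradients.

Each per-sample update of the embedding trainer is an exact gradient-ascent
step on one term of the joint objective; this module measures the worst
relative deviation from central finite differences over random instances.
"""

from __future__ import annotations

import numpy as np

from mirdrug.bine import (
    BineConfig,
    NodeEmbeddingTable,
    sga_step_explicit,
    sga_step_implicit,
    sigmoid,
)
from mirdrug.graph import BipartiteGraph


def numeric_grad(f, x, eps: float = 1e-6) -> np.ndarray:
    g = np.zeros_like(x)
    for k in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[k] += eps
        xm[k] -= eps
        g[k] = (f(xp) - f(xm)) / (2 * eps)
    return g


def max_gradient_error(n_instances: int = 100, seed: int = 0) -> float:
    """Worst relative error between each SGA update and the finite-difference
    gradient of its objective term, over random small instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0

    def relerr(update, grad):
        return np.abs(update - grad).max() / max(np.abs(grad).max(), 1e-12)

    for _ in range(n_instances):
        dim = int(rng.integers(2, 6))
        lr = float(rng.uniform(0.01, 0.1))
        w = float(rng.uniform(0.5, 2.0))
        gamma, alpha = float(rng.uniform(0.5, 2.0)), float(rng.uniform(0.5, 2.0))

        # explicit term: gamma * w * log sigma(d.m)
        d, m = rng.normal(size=dim), rng.normal(size=dim)
        g = BipartiteGraph(["d"], ["m"], {(0, 0): w})
        cfg = BineConfig(dim=dim, lr=lr, gamma=gamma, alpha=alpha, beta=alpha)
        emb = NodeEmbeddingTable(np.array([d]), np.array([m]),
                                 np.zeros((1, dim)), np.zeros((1, dim)))
        sga_step_explicit(emb, g, 0, 0, cfg)
        worst = max(worst, relerr(
            emb.drug_vecs[0] - d,
            lr * numeric_grad(lambda x: gamma * w * np.log(sigmoid(x @ m)), d)))
        worst = max(worst, relerr(
            emb.mirna_vecs[0] - m,
            lr * numeric_grad(lambda x: gamma * w * np.log(sigmoid(d @ x)), m)))

        # implicit term: alpha * [log sigma(v.th+) + log(1 - sigma(v.th-))]
        v = rng.normal(size=dim)
        th = rng.normal(size=(3, dim))
        emb = NodeEmbeddingTable(np.vstack([v, np.zeros((2, dim))]),
                                 np.zeros((1, dim)), th.copy(), np.zeros((1, dim)))
        sga_step_implicit(emb, 0, [(1, True), (2, False)], "drug", cfg)
        obj = lambda x: alpha * (np.log(sigmoid(x @ th[1])) + np.log(1 - sigmoid(x @ th[2])))
        worst = max(worst, relerr(emb.drug_vecs[0] - v, lr * numeric_grad(obj, v)))
        worst = max(worst, relerr(
            emb.drug_ctx[1] - th[1],
            lr * numeric_grad(lambda t: alpha * np.log(sigmoid(v @ t)), th[1])))
        worst = max(worst, relerr(
            emb.drug_ctx[2] - th[2],
            lr * numeric_grad(lambda t: alpha * np.log(1 - sigmoid(v @ t)), th[2])))
    return worst
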