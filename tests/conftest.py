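import numpy as np
import pytest

from mirdrug.features import AttributeFeatureTable, kmer_featurize, maccs_featurize
from mirdrug.fixtures import FixtureSpec, gen_bipartite, gen_drug_table, gen_sequences
from mirdrug.graph import BipartiteGraph


@pytest.fixture
def toy_graph():
    """2 drugs x 2 miRNAs with W = [[1, 1], [0, 1]]."""
    return BipartiteGraph(["d1", "d2"], ["m1", "m2"], {(0, 0): 1.0, (0, 1): 1.0, (1, 1): 1.0})


@pytest.fixture
def identity_graph():
    return BipartiteGraph(["d1", "d2"], ["m1", "m2"], {(0, 0): 1.0, (1, 1): 1.0})


def random_bipartite(rng, n_drugs, n_mirnas, density=0.3, weighted=False) -> BipartiteGraph:
    edges = {}
    for i in range(n_drugs):
        for j in range(n_mirnas):
            if rng.random() < density:
                edges[(i, j)] = float(rng.integers(1, 5)) if weighted else 1.0
    if not edges:
        edges[(0, 0)] = 1.0
    return BipartiteGraph(
        [f"d{i}" for i in range(n_drugs)], [f"m{j}" for j in range(n_mirnas)], edges
    )


@pytest.fixture
def small_planted_dataset():
    """In-memory dataset on a small, strongly separable planted-block graph.

    Within-block density 0.9 keeps within-block non-edges rare, so held-out
    edges are rankable nearly perfectly from topology.
    """
    from mirdrug.fixtures import make_dataset

    spec = FixtureSpec(n_drugs=20, n_mirnas=40, p_within=0.9, p_between=0.01,
                       seq_len_range=(20, 25), seed=11)
    return make_dataset(spec)


def block_informative_dataset(seed=5, n_drugs=20, n_mirnas=40, p_within=0.8, p_between=0.02):
    """Planted-block dataset whose ATTRIBUTES also encode the block.

    Block-0 drugs share one molecule and block-1 drugs another; miRNA
    sequences are composition-biased per block.  Used to exercise cold-start
    protocols, where only attributes can carry signal.
    """
    from mirdrug.evaluation import MdiDataset

    spec = FixtureSpec(n_drugs=n_drugs, n_mirnas=n_mirnas, n_blocks=2,
                       p_within=p_within, p_between=p_between, seed=seed)
    g, db, mb = gen_bipartite(spec)
    rng = np.random.default_rng(seed + 1)
    block_smiles = ["CC(=O)OC1=CC=CC=C1C(=O)O", "CN1C=NC2=C1C(=O)N(C)C(=O)N2C"]
    table = AttributeFeatureTable()
    for i, d in enumerate(g.drug_ids):
        table.drug[d] = maccs_featurize(block_smiles[db[i]])
    alphabets = [np.array(list("AAAGCU")), np.array(list("GGGUCA"))]
    for j, m in enumerate(g.mirna_ids):
        seq = "".join(rng.choice(alphabets[mb[j]], size=25))
        table.mirna[m] = kmer_featurize(seq)
    return MdiDataset(graph=g, attributes=table), db, mb
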