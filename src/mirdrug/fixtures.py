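"""Synthetic data generation: planted-block bipartite graphs, random RNA
sequences, and drug tables with valid SMILES.

The generator emulates the regimes the predictor assumes — a sparse
bipartite interaction network with recoverable structure (planted blocks),
short miRNA-like sequences (20-25 nt by default), and real parseable drug
SMILES — so the whole pipeline is testable without external downloads.  It
makes no attempt at biological realism beyond that.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from mirdrug.features import AttributeFeatureTable, kmer_featurize, maccs_featurize
from mirdrug.graph import BipartiteGraph

#: drug-like molecules used to assign fixture drugs a valid SMILES
BUILTIN_SMILES = [
    "CCO",  # ethanol
    "CC(=O)OC1=CC=CC=C1C(=O)O",  # aspirin
    "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",  # caffeine
    "CC(C)CC1=CC=C(C=C1)C(C)C(=O)O",  # ibuprofen
    "CC(=O)NC1=CC=C(O)C=C1",  # acetaminophen
    "C1=C(C(=O)NC(=O)N1)F",  # 5-fluorouracil
    "CN1CCC[C@H]1c1cccnc1",  # nicotine
    "CCOC(=O)c1ccc(N)cc1",  # benzocaine
    "CN(C)C(=N)NC(=N)N",  # metformin
    "OC(=O)c1ccccc1O",  # salicylic acid
    "NC(=O)c1cccnc1",  # nicotinamide
    "OCC(O)CO",  # glycerol
    "CC(C)NCC(O)COc1cccc2ccccc12",  # propranolol
    "Nc1ccc(cc1)S(N)(=O)=O",  # sulfanilamide
    "OC(=O)CC(O)(CC(=O)O)C(=O)O",  # citric acid
    "C1CCNCC1",  # piperidine
    "c1ccc2[nH]ccc2c1",  # indole
    "NC(Cc1ccccc1)C(=O)O",  # phenylalanine
    "CSCCC(N)C(=O)O",  # methionine
    "Nc1ncnc2[nH]cnc12",  # adenine
    "Cc1ccc(cc1)S(N)(=O)=O",  # p-toluenesulfonamide
    "CC(=O)Oc1ccccc1",  # phenyl acetate
    "OCc1ccccc1",  # benzyl alcohol
    "CC(N)Cc1ccccc1",  # amphetamine
    "NCCc1ccc(O)c(O)c1",  # dopamine
    "CNC[C@H](O)c1ccc(O)c(O)c1",  # epinephrine
    "NCCc1ccc(O)cc1",  # tyramine
    "CC(C)(C)NC[C@@H](O)c1ccc(O)c(CO)c1",  # salbutamol
    "O=c1cc[nH]c(=O)[nH]1",  # uracil
    "Cn1cnc2c1c(=O)[nH]c(=O)n2C",  # theobromine
    "NC(N)=O",  # urea
    "CC(C)=O",  # acetone
    "c1ccncc1",  # pyridine
    "OC(=O)c1cccnc1",  # niacin
    "NCCCCC(N)C(=O)O",  # lysine
]


@dataclass
class FixtureSpec:
    """Conditions of the synthetic benchmark.

    Defaults: 60 drugs x 120 miRNAs in 2 planted blocks with within-block
    edge probability 0.3 and cross-block probability 0.01, miRNA-like
    sequence lengths 20-25 nt.
    """

    n_drugs: int = 60
    n_mirnas: int = 120
    n_blocks: int = 2
    p_within: float = 0.3
    p_between: float = 0.01
    seq_len_range: tuple[int, int] = (20, 25)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_between <= self.p_within <= 1):
            raise ValueError("require 0 <= p_between <= p_within <= 1")
        if self.n_blocks > min(self.n_drugs, self.n_mirnas):
            raise ValueError("more blocks than nodes on a side")
        lo, hi = self.seq_len_range
        if not (3 <= lo <= hi <= 500):
            raise ValueError("seq_len_range must lie within [3, 500]")

    def with_(self, **kw) -> "FixtureSpec":
        return replace(self, **kw)


def _block_assignment(n: int, n_blocks: int) -> np.ndarray:
    return np.arange(n) % n_blocks


def gen_bipartite(spec: FixtureSpec) -> tuple[BipartiteGraph, np.ndarray, np.ndarray]:
    """Planted-block bipartite graph; returns (graph, drug_blocks, mirna_blocks).

    Nodes are assigned to blocks round-robin; each (drug, miRNA) pair gets an
    edge independently with probability p_within (same block) or p_between.
    """
    rng = np.random.default_rng(spec.seed)
    db = _block_assignment(spec.n_drugs, spec.n_blocks)
    mb = _block_assignment(spec.n_mirnas, spec.n_blocks)
    prob = np.where(db[:, None] == mb[None, :], spec.p_within, spec.p_between)
    mask = rng.random((spec.n_drugs, spec.n_mirnas)) < prob
    edges = {(int(i), int(j)): 1.0 for i, j in zip(*np.nonzero(mask))}
    width_d = len(str(max(spec.n_drugs - 1, 1)))
    width_m = len(str(max(spec.n_mirnas - 1, 1)))
    g = BipartiteGraph(
        drug_ids=[f"D{i:0{width_d}d}" for i in range(spec.n_drugs)],
        mirna_ids=[f"M{j:0{width_m}d}" for j in range(spec.n_mirnas)],
        edges=edges,
    )
    return g, db, mb


def gen_sequences(n: int, len_range: tuple[int, int], rng, ids=None) -> list[tuple[str, str]]:
    """Uniform random RNA sequences; lengths uniform in ``len_range``."""
    lo, hi = len_range
    if not (3 <= lo <= hi <= 500):
        raise ValueError("len_range must lie within [3, 500]")
    if ids is None:
        width = len(str(max(n - 1, 1)))
        ids = [f"M{j:0{width}d}" for j in range(n)]
    alphabet = np.array(list("ACGU"))
    records = []
    for nid in ids[:n]:
        L = int(rng.integers(lo, hi + 1))
        records.append((nid, "".join(rng.choice(alphabet, size=L))))
    return records


def gen_drug_table(n: int, rng, ids=None) -> pd.DataFrame:
    """Drug table assigning each synthetic drug a SMILES from the built-in
    list (sampling with replacement beyond the list size)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if ids is None:
        width = len(str(max(n - 1, 1)))
        ids = [f"D{i:0{width}d}" for i in range(n)]
    smiles = [BUILTIN_SMILES[int(k)] for k in rng.integers(len(BUILTIN_SMILES), size=n)]
    return pd.DataFrame({"drug_id": ids[:n], "smiles": smiles})


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for nid, seq in records:
            fh.write(f">{nid}\n{seq}\n")


def write_fixture_files(spec: FixtureSpec, outdir) -> dict[str, str]:
    """Emit the three pipeline input files (edge TSV, FASTA, drug CSV)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g, _, _ = gen_bipartite(spec)
    rng = np.random.default_rng(spec.seed + 1)
    records = gen_sequences(spec.n_mirnas, spec.seq_len_range, rng, ids=g.mirna_ids)
    drugs = gen_drug_table(spec.n_drugs, rng, ids=g.drug_ids)

    edges_path = outdir / "edges.tsv"
    with open(edges_path, "w") as fh:
        fh.write("# drug_id\tmirna_id\tweight\n")
        for (i, j), w in sorted(g.edges.items()):
            fh.write(f"{g.drug_ids[i]}\t{g.mirna_ids[j]}\t{w:g}\n")
    fasta_path = outdir / "mirnas.fasta"
    write_fasta(records, fasta_path)
    drugs_path = outdir / "drugs.csv"
    drugs.to_csv(drugs_path, index=False)
    return {"edges": str(edges_path), "fasta": str(fasta_path), "drugs": str(drugs_path)}


def make_attribute_table(records, drug_table: pd.DataFrame) -> AttributeFeatureTable:
    """In-memory featurization of generated fixtures (no files involved)."""
    table = AttributeFeatureTable()
    for nid, seq in records:
        table.mirna[nid] = kmer_featurize(seq)
    cache: dict[str, np.ndarray] = {}
    for _, row in drug_table.iterrows():
        smi = row["smiles"]
        if smi not in cache:
            cache[smi] = maccs_featurize(smi)
        table.drug[row["drug_id"]] = cache[smi]
    return table


def make_dataset(spec: FixtureSpec):
    """Full in-memory synthetic dataset: (MdiDataset, drug_blocks, mirna_blocks)."""
    from mirdrug.evaluation import MdiDataset

    g, db, mb = gen_bipartite(spec)
    rng = np.random.default_rng(spec.seed + 1)
    records = gen_sequences(spec.n_mirnas, spec.seq_len_range, rng, ids=g.mirna_ids)
    drugs = gen_drug_table(spec.n_drugs, rng, ids=g.drug_ids)
    dataset = MdiDataset(graph=g, attributes=make_attribute_table(records, drugs))
    return dataset, db, mb
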