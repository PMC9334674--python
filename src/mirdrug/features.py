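"""Attribute featurization: miRNA 3-mer composition and drug MACCS keys.

miRNA sequences become normalized k-mer frequency vectors (k = 3 over the
RNA alphabet {A, C, G, U} gives 64 entries summing to 1); drug SMILES become
the 166 defined MACCS substructure keys as a Boolean vector (the reference
implementation's unused bit 0 is dropped).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys

RDLogger.DisableLog("rdApp.*")  # rdkit parse chatter; failures are raised instead

logger = logging.getLogger(__name__)

RNA_ALPHABET = "ACGU"
N_MACCS_KEYS = 166


def kmer_names(k: int = 3) -> list[str]:
    """Lexicographic k-mers over {A, C, G, U}."""
    return ["".join(p) for p in itertools.product(RNA_ALPHABET, repeat=k)]


def kmer_featurize(sequence: str, k: int = 3) -> np.ndarray:
    """Normalized k-mer frequencies of an RNA sequence (sliding window, step 1).

    Case-insensitive; DNA spelling (T) is mapped to U.  Characters outside
    {A, C, G, U, T} are rejected with the offending position, as are
    sequences shorter than k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = sequence.strip().upper().replace("T", "U")
    for pos, ch in enumerate(seq):
        if ch not in RNA_ALPHABET:
            raise ValueError(f"invalid character {ch!r} at position {pos} in sequence")
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} is shorter than k={k}")
    index = {km: i for i, km in enumerate(kmer_names(k))}
    vec = np.zeros(4**k)
    for t in range(len(seq) - k + 1):
        vec[index[seq[t : t + k]]] += 1
    return vec / (len(seq) - k + 1)


def maccs_featurize(smiles: str) -> np.ndarray:
    """166-key MACCS substructure fingerprint of a SMILES string (uint8 0/1)."""
    if not smiles or not smiles.strip():
        raise ValueError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    fp = MACCSkeys.GenMACCSKeys(mol)  # 167 bits; bit 0 is unused by convention
    bits = np.zeros(N_MACCS_KEYS, dtype=np.uint8)
    for b in fp.GetOnBits():
        if b >= 1:
            bits[b - 1] = 1
    return bits


@dataclass
class AttributeFeatureTable:
    """Per-node attribute vectors plus a log of rejected records."""

    mirna: dict[str, np.ndarray] = field(default_factory=dict)
    drug: dict[str, np.ndarray] = field(default_factory=dict)
    rejects: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    @property
    def kmer_dim(self) -> int:
        return len(next(iter(self.mirna.values()))) if self.mirna else 4**3

    def write_tsv(self, mirna_path, drug_path) -> None:
        _write_feature_tsv(mirna_path, self.mirna, kmer_names(_k_from_dim(self.kmer_dim)))
        _write_feature_tsv(drug_path, self.drug, [f"maccs_{i}" for i in range(1, N_MACCS_KEYS + 1)])

    @classmethod
    def read_tsv(cls, mirna_path, drug_path) -> "AttributeFeatureTable":
        return cls(
            mirna=_read_feature_tsv(mirna_path, float),
            drug=_read_feature_tsv(drug_path, lambda x: np.uint8(float(x))),
        )


def _k_from_dim(dim: int) -> int:
    k = int(round(np.log(dim) / np.log(4)))
    if 4**k != dim:
        raise ValueError(f"k-mer vector length {dim} is not a power of 4")
    return k


def _write_feature_tsv(path, table: dict[str, np.ndarray], colnames: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(colnames) + "\n")
        for nid, vec in table.items():
            fh.write(str(nid) + "\t" + "\t".join(repr(float(v)) for v in vec) + "\n")


def _read_feature_tsv(path, cast) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            out[parts[0]] = np.array([cast(v) for v in parts[1:]])
    return out


def read_drug_table(path) -> pd.DataFrame:
    """Drug table with columns ``drug_id`` and ``smiles`` (CSV or TSV)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "drug_id" not in cols or "smiles" not in cols:
        raise ValueError(f"{path}: drug table needs columns drug_id, smiles")
    return df.rename(columns={cols["drug_id"]: "drug_id", cols["smiles"]: "smiles"})


def featurize_tables(fasta_path, drug_table_path, k: int = 3) -> AttributeFeatureTable:
    """Featurize all miRNA FASTA records and drug table rows.

    Records failing validation (bad characters, short sequences, unparsable
    SMILES) are skipped, logged, and reported in ``rejects``; duplicate IDs
    are an error.
    """
    table = AttributeFeatureTable()
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if not rec.id:
            raise ValueError(f"{fasta_path}: FASTA record with empty id")
        if rec.id in seen:
            raise ValueError(f"{fasta_path}: duplicate miRNA id {rec.id!r}")
        seen.add(rec.id)
        try:
            table.mirna[rec.id] = kmer_featurize(str(rec.seq), k=k)
        except ValueError as exc:
            logger.warning("skipping miRNA %s: %s", rec.id, exc)
            table.rejects.append((rec.id, str(exc)))

    df = read_drug_table(drug_table_path)
    if df["drug_id"].duplicated().any():
        dup = df.loc[df["drug_id"].duplicated(), "drug_id"].iloc[0]
        raise ValueError(f"{drug_table_path}: duplicate drug id {dup!r}")
    for _, row in df.iterrows():
        try:
            table.drug[row["drug_id"]] = maccs_featurize(row["smiles"])
        except ValueError as exc:
            logger.warning("skipping drug %s: %s", row["drug_id"], exc)
            table.rejects.append((row["drug_id"], str(exc)))
    return table
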