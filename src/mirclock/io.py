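"""Readers/writers for the plain-text formats the pipeline exchanges.

Matrices are TSV with samples as rows (index column ``sample_id``); pedigrees
are PED-like TSV with founder marker ``0``; kinship is long-format TSV;
sequences are FASTA (via Biopython); gene sets are GMT.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mirclock.exceptions import ConfigurationError

PEDIGREE_COLUMNS = ["pedigree_id", "individual_id", "father_id", "mother_id", "sex"]
FOUNDER = "0"


def write_matrix_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_matrix_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_phenotypes(phen: pd.DataFrame, path: str | os.PathLike) -> None:
    phen.to_csv(path, sep="\t", index_label="sample_id")


def read_phenotypes(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def validate_pedigree(ped: pd.DataFrame) -> None:
    """Check structural invariants: unique ids, resolvable acyclic parent
    links within each pedigree, fathers male and mothers female."""
    missing = [c for c in PEDIGREE_COLUMNS if c not in ped.columns]
    if missing:
        raise ConfigurationError(f"pedigree table lacks columns: {missing}")
    if ped["individual_id"].duplicated().any():
        dups = ped.loc[ped["individual_id"].duplicated(), "individual_id"].tolist()
        raise ConfigurationError(f"duplicate individual_ids: {dups[:5]}")
    sex = dict(zip(ped["individual_id"], ped["sex"]))
    fam = dict(zip(ped["individual_id"], ped["pedigree_id"]))
    for _, row in ped.iterrows():
        for parent_col, want in (("father_id", "male"), ("mother_id", "female")):
            pid = row[parent_col]
            if pid == FOUNDER:
                continue
            if pid not in sex:
                raise ConfigurationError(
                    f"{row['individual_id']}: unknown {parent_col} {pid!r}"
                )
            if fam[pid] != row["pedigree_id"]:
                raise ConfigurationError(
                    f"{row['individual_id']}: parent {pid} in a different pedigree"
                )
            if sex[pid] != want:
                raise ConfigurationError(
                    f"{row['individual_id']}: {parent_col} {pid} has sex {sex[pid]!r}"
                )
    # acyclicity via iterative resolution (founders first)
    placed: set[str] = set()
    pending = list(ped.itertuples(index=False))
    while pending:
        progress = []
        for row in pending:
            fa, mo = row.father_id, row.mother_id
            if (fa == FOUNDER or fa in placed) and (mo == FOUNDER or mo in placed):
                placed.add(row.individual_id)
            else:
                progress.append(row)
        if len(progress) == len(pending):
            ids = [r.individual_id for r in progress]
            raise ConfigurationError(f"cyclic pedigree involving: {ids[:5]}")
        pending = progress


def write_pedigree(ped: pd.DataFrame, path: str | os.PathLike) -> None:
    ped[PEDIGREE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | os.PathLike) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t", dtype=str)
    validate_pedigree(ped)
    return ped


def write_kinship_long(K: pd.DataFrame, path: str | os.PathLike, tol: float = 0.0) -> None:
    """Long-format kinship: id1, id2, value; only the upper triangle with
    value > tol plus the diagonal is stored."""
    rows = []
    ids = list(K.index)
    vals = K.values
    for i, a in enumerate(ids):
        for j in range(i, len(ids)):
            v = vals[i, j]
            if i == j or v > tol:
                rows.append((a, ids[j], v))
    pd.DataFrame(rows, columns=["id1", "id2", "value"]).to_csv(path, sep="\t", index=False)


def read_kinship_long(path: str | os.PathLike) -> pd.DataFrame:
    long = pd.read_csv(path, sep="\t", dtype={"id1": str, "id2": str})
    ids = pd.unique(pd.concat([long["id1"], long["id2"]]))
    K = pd.DataFrame(0.0, index=ids, columns=ids)
    for a, b, v in long.itertuples(index=False):
        K.loc[a, b] = v
        K.loc[b, a] = v
    return K


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(seqs, os.fspath(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_gmt(gene_sets: dict[str, list[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = [g for g in parts[2:] if g]
    return out
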