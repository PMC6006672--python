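"""Standard-format adapters: FASTA, BED6, newick and commented TSV.

All coordinates are 0-based half-open. TSV artifacts written by the
pipeline carry ``# key=value`` header comments (config hash, seed) that
the readers skip transparently.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from .smallrna import SmallRNARead

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_tsv",
    "write_tsv",
    "read_newick",
    "write_newick",
    "reads_from_bed",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> ordered {id: sequence}."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path) -> pd.DataFrame:
    """6-column BED -> DataFrame with 0-based half-open coordinates."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=BED_COLUMNS,
        dtype={"chrom": str, "name": str, "strand": str},
    )
    bad = df[(df.start < 0) | (df.end <= df.start)]
    if not bad.empty:
        raise ValueError(
            f"malformed BED record at line {bad.index[0] + 1}: "
            f"{bad.iloc[0].tolist()}"
        )
    return df


def write_bed(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=BED_COLUMNS)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_tsv(path, df: pd.DataFrame, header_comments: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, value in (header_comments or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_newick(source) -> TreeNode:
    if isinstance(source, (str, Path)) and Path(source).exists():
        return TreeNode.read(str(source))
    return TreeNode.read(_io.StringIO(str(source)))


def write_newick(path, tree: TreeNode) -> None:
    tree.write(str(path))


def reads_from_bed(df: pd.DataFrame, sequences: dict[str, str] | None = None
                   ) -> list[SmallRNARead]:
    """BED rows -> SmallRNARead records.

    chrom is the TE id, name the read id; length = end - start. Optional
    ``sequences`` maps read names to read-orientation sequences.
    """
    sequences = sequences or {}
    reads = []
    for row in df.itertuples(index=False):
        reads.append(SmallRNARead(
            te_id=row.chrom,
            start=int(row.start),
            length=int(row.end) - int(row.start),
            strand=row.strand,
            sequence=sequences.get(row.name, ""),
        ))
    return reads
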