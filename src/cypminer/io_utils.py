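"""Small FASTA/TSV helpers and packaged-data loaders."""

from __future__ import annotations

import importlib.resources as resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> ordered {id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    """Write sequences wrapped at 60 columns."""
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def _data_path(name: str) -> Path:
    return Path(resources.files("cypminer").joinpath("data", name))


def load_domain_consensus() -> str:
    """The packaged 463-residue CYP domain consensus.

    This is a synthetic stand-in for a profile-derived domain consensus: a
    fixed random protein with the four conserved CYP motifs embedded at
    realistic offsets.  It is a data file and can be swapped for a real
    profile consensus without code changes.
    """
    seqs = read_fasta(_data_path("cyp_domain_consensus_synthetic.fasta"))
    (seq,) = seqs.values()
    return seq


def load_packaged_gene_table() -> pd.DataFrame:
    """The packaged 116-row full-length CYP450 gene table fixture."""
    return read_tsv(_data_path("gene_table.tsv"))
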