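"""FASTA input/output and the tab-separated match record dialect."""

from __future__ import annotations

from typing import Iterable, NamedTuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_fasta", "write_fasta", "LemRecord", "write_tsv"]

TSV_HEADER = ("pattern_id", "p_start", "t_seq_id", "t_offset", "length")


def read_fasta(path):
    """All records of a FASTA file as (name, sequence-string) pairs."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path!r}")
    return records


def write_fasta(path, records: Iterable):
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        path,
        "fasta",
    )


class LemRecord(NamedTuple):
    """One reported match, in per-sequence coordinates (1-based inclusive)."""

    pattern_id: str
    p_start: int
    t_seq_id: str
    t_offset: int
    length: int


def write_tsv(records, sink):
    """Write sorted match records with a header line."""
    own = isinstance(sink, str)
    fh = open(sink, "w") if own else sink
    try:
        fh.write("\t".join(TSV_HEADER) + "\n")
        for rec in records:
            fh.write("\t".join(str(v) for v in rec) + "\n")
    finally:
        if own:
            fh.close()
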