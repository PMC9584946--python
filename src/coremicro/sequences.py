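"""Representative-sequence sets (FASTA in/out) for OTUs and ZOTUs."""

from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_fasta", "write_fasta", "validate_sequences"]

_ALPHABET = set("ACGTN")


def validate_sequences(seqs: dict[str, str]) -> dict[str, str]:
    """Validate a representative-sequence mapping (unique ids, ACGTN, non-empty)."""
    out = {}
    for sid, seq in seqs.items():
        s = str(seq).upper()
        if not s:
            raise ValueError(f"empty sequence for {sid!r}")
        bad = set(s) - _ALPHABET
        if bad:
            raise ValueError(f"non-nucleotide characters {sorted(bad)} in {sid!r}")
        if sid in out:
            raise ValueError(f"duplicate sequence id {sid!r}")
        out[str(sid)] = s
    return out


def read_fasta(path) -> dict[str, str]:
    seqs = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValueError(f"duplicate sequence id {record.id!r} in {path!r}")
        seqs[record.id] = str(record.seq).upper()
    return validate_sequences(seqs)


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=sid, description="") for sid, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
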