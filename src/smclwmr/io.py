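"""FASTA input and report serialisation."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqcore import DNA, Alphabet

__all__ = ["read_fasta", "write_fasta", "write_report"]


def read_fasta(path, alphabet: Alphabet = DNA, with_ids: bool = False):
    """Sequences from a multi-FASTA file, validated against the alphabet.

    Characters are case-insensitive; anything outside the alphabet is
    rejected with the record name and 1-based position. An empty file
    returns an empty list with a warning.
    """
    path = Path(path)
    allowed = set(alphabet.symbols.upper())
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        for pos, c in enumerate(s):
            if c not in allowed:
                raise ValueError(
                    f"{path.name}: record {rec.id!r} has invalid character "
                    f"{c!r} at position {pos + 1}"
                )
        ids.append(rec.id)
        seqs.append(s)
    if not seqs:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return (ids, seqs) if with_ids else seqs


def write_fasta(seqs, path, ids=None) -> None:
    ids = ids or [f"seq{i}" for i in range(len(seqs))]
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in zip(ids, seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_report(reports, prefix, one_based: bool = False) -> None:
    """Write motif reports as <prefix>.tsv and <prefix>.json.

    Offsets are 0-based half-open by default; ``one_based`` shifts starts
    by +1 for 1-based coordinate consumers.
    """
    prefix = Path(prefix)
    shift = 1 if one_based else 0
    rows = []
    for rank, r in enumerate(reports):
        rows.append(
            {
                "rank": rank,
                "consensus": r.consensus,
                "weight": r.weight,
                "max_distance": r.max_distance,
                "classification_path": r.classification_path,
                "occurrences": ";".join(
                    f"{i}:{j + shift}" for i, j in r.occurrences
                ),
            }
        )
    with open(prefix.with_suffix(".tsv"), "w") as fh:
        cols = ["rank", "consensus", "weight", "max_distance",
                "classification_path", "occurrences"]
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    payload = [
        {
            "rank": row["rank"],
            "consensus": row["consensus"],
            "weight": row["weight"],
            "max_distance": row["max_distance"],
            "classification_path": row["classification_path"],
            "occurrences": [
                {"string": i, "offset": j + shift} for i, j in r.occurrences
            ],
        }
        for row, r in zip(rows, reports)
    ]
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump({"one_based": one_based, "reports": payload}, fh, indent=2)
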