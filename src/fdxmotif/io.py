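"""FASTA input and tabular report output.

Reports use 1-based inclusive coordinates by default (the common motif-report
convention); internal coordinates are 0-based half-open throughout the
package.  All writers emit fixed column orders so identical inputs produce
byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .scanner import MotifHit

__all__ = [
    "FastaError",
    "read_fasta",
    "write_fasta",
    "hits_to_frame",
    "write_hits_tsv",
    "HIT_COLUMNS",
]

#: residues accepted in input sequences: the 20 standard amino acids plus
#: ambiguity/rare codes (legal, but never matching a motif position)
LEGAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYBXZJUO*")

HIT_COLUMNS = [
    "sequence_id",
    "cluster_type",
    "subtype_label",
    "signature",
    "start_1based",
    "end_1based",
    "cys_positions",
]


class FastaError(ValueError):
    """Unreadable or malformed FASTA; the message names the record."""


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly line-wrapped, multi-record) FASTA file.

    Sequences are uppercased and validated against the amino-acid alphabet;
    an illegal character raises :class:`FastaError` naming the record number
    and id.  Returns (id, sequence) pairs in file order.
    """
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (OSError, ValueError) as exc:
        raise FastaError(f"cannot read FASTA {path}: {exc}") from exc
    out = []
    for i, rec in enumerate(records, start=1):
        seq = str(rec.seq).upper().replace("-", "")
        bad = set(seq) - LEGAL_RESIDUES
        if bad:
            raise FastaError(
                f"record {i} ({rec.id}): illegal character(s) {sorted(bad)} in sequence"
            )
        out.append((rec.id, seq))
    return out


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    SeqIO.write(list(records), str(path), "fasta")


def hits_to_frame(
    hits: Iterable[MotifHit],
    labels: dict | None = None,
    one_based: bool = True,
) -> pd.DataFrame:
    """Tabulate hits; ``labels`` maps (sequence_id, hit index) -> subtype label."""
    off = 1 if one_based else 0
    rows = []
    for k, h in enumerate(hits):
        rows.append(
            {
                "sequence_id": h.sequence_id,
                "cluster_type": h.cluster_type.value,
                "subtype_label": (labels or {}).get(k, ""),
                "signature": str(h.signature),
                "start_1based" if one_based else "start_0based": h.start + off,
                "end_1based" if one_based else "end_0based": h.end if one_based else h.end,
                "cys_positions": ",".join(str(p + off) for p in h.cys_positions),
            }
        )
    cols = list(HIT_COLUMNS)
    if not one_based:
        cols = [c.replace("_1based", "_0based") for c in cols]
    return pd.DataFrame(rows, columns=cols)


def write_hits_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
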