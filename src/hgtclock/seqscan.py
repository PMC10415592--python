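"""C-X-X-C-H heme-binding motif census of protein FASTA proteomes.

Multiheme c-type cytochromes (MHCs) bind their hemes through the
five-residue signature cysteine, any, any, cysteine, histidine.  A
protein carrying at least ``min_motifs`` such motifs (default 2, i.e. at
least two hemes) is classified as an MHC.  The census reports, per
proteome, the number of MHCs and the total number of heme-binding motifs
carried by those MHCs.

Matching is purely positional: only the two C positions and the H
position are constrained, the two X positions accept any residue symbol
(including ambiguity codes).  Stop (``*``) and gap (``-``) symbols never
match any motif position.  Overlapping occurrences are all counted.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

__all__ = [
    "MOTIF_LENGTH",
    "ProteinRecord",
    "MotifHit",
    "ProteomeSummary",
    "read_fasta",
    "scan_heme_motifs",
    "count_heme_motifs",
    "classify_proteome",
    "per_protein_frame",
    "summary_frame",
]

MOTIF_LENGTH = 5


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry: id (first header token), description, residues."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class MotifHit:
    """One C-X-X-C-H occurrence at a 0-based start index."""

    protein_id: str
    start: int
    length: int = MOTIF_LENGTH


@dataclass(frozen=True)
class ProteomeSummary:
    genome_id: str
    n_proteins: int
    n_mhc: int
    n_motifs_in_mhc: int
    per_protein: dict[str, int]
    min_motifs: int = 2


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA (optionally gzip-compressed) into records.

    One record per header, multi-line sequences concatenated, input
    order preserved.  The record id is the first whitespace-delimited
    token of the header.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[ProteinRecord] = []
    with opener(path, "rt") as fh:
        # reject sequence data appearing before any header
        pos = fh.tell()
        first = fh.readline()
        while first and not first.strip():
            pos = fh.tell()
            first = fh.readline()
        if first and not first.startswith(">"):
            raise ValueError(
                f"{path}: sequence line before any FASTA header: {first.strip()!r}"
            )
        fh.seek(pos)
        for rec in SeqIO.parse(fh, "fasta"):
            records.append(
                ProteinRecord(
                    id=rec.id,
                    description=rec.description,
                    sequence=str(rec.seq),
                )
            )
    return records


def scan_heme_motifs(sequence: str, protein_id: str = "") -> list[MotifHit]:
    """All C-X-X-C-H occurrences in a residue string, sorted by start.

    Every start index is examined, so overlapping hits are all reported.
    Matching is case-insensitive; a sequence shorter than the motif
    yields an empty list.
    """
    seq = sequence.upper()
    hits = []
    for i in range(len(seq) - MOTIF_LENGTH + 1):
        if seq[i] == "C" and seq[i + 3] == "C" and seq[i + 4] == "H":
            # X positions accept any residue symbol except stop/gap
            if seq[i + 1] in "*-" or seq[i + 2] in "*-":
                continue
            hits.append(MotifHit(protein_id=protein_id, start=i))
    return hits


def count_heme_motifs(sequence: str) -> int:
    return len(scan_heme_motifs(sequence))


def classify_proteome(
    records: Iterable[ProteinRecord],
    min_motifs: int = 2,
    genome_id: str = "",
) -> ProteomeSummary:
    """Census one proteome: count MHCs and the motifs they carry.

    ``n_mhc`` counts proteins with at least ``min_motifs`` motifs;
    ``n_motifs_in_mhc`` sums motif counts over those proteins only
    (motifs in sub-threshold proteins are not part of the census total).
    """
    if min_motifs < 1:
        raise ValueError(f"min_motifs must be >= 1, got {min_motifs}")
    per_protein: dict[str, int] = {}
    for rec in records:
        if rec.id in per_protein:
            raise ValueError(f"duplicate protein id {rec.id!r} in proteome {genome_id!r}")
        per_protein[rec.id] = len(scan_heme_motifs(rec.sequence, rec.id))
    n_mhc = sum(1 for c in per_protein.values() if c >= min_motifs)
    n_motifs_in_mhc = sum(c for c in per_protein.values() if c >= min_motifs)
    return ProteomeSummary(
        genome_id=genome_id,
        n_proteins=len(per_protein),
        n_mhc=n_mhc,
        n_motifs_in_mhc=n_motifs_in_mhc,
        per_protein=per_protein,
        min_motifs=min_motifs,
    )


def per_protein_frame(summary: ProteomeSummary) -> pd.DataFrame:
    """Per-protein table: genome_id, protein_id, n_motifs, is_mhc."""
    return pd.DataFrame(
        {
            "genome_id": summary.genome_id,
            "protein_id": list(summary.per_protein),
            "n_motifs": list(summary.per_protein.values()),
            "is_mhc": [
                c >= summary.min_motifs for c in summary.per_protein.values()
            ],
        }
    )


def summary_frame(summary: ProteomeSummary) -> pd.DataFrame:
    """One-row census table: genome_id, n_proteins, n_mhc, n_motifs_in_mhc."""
    return pd.DataFrame(
        [
            {
                "genome_id": summary.genome_id,
                "n_proteins": summary.n_proteins,
                "n_mhc": summary.n_mhc,
                "n_motifs_in_mhc": summary.n_motifs_in_mhc,
            }
        ]
    )
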