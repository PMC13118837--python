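"""Pan-proteome ingestion and bookkeeping.

A pan-proteome is the redundant union (R-D) of all per-genome protein FASTA
files.  Collapsing records that share an accession ID yields the
non-redundant dataset (NR-D), while recording in how many genomes each ID
occurs (occurrence count) and how many records carry it in total
(total copies; the same accession may appear more than once within a genome
for paralogs sharing a multispecies accession).  Partitioning the NR-D by a
KO annotation table separates annotated proteins from the non-redundant
unannotated dataset (NR-U-D) that feeds clustering.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")
KO_PATTERN = re.compile(r"^K\d+$")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence from one genome's predicted proteome."""

    protein_id: str
    genome_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.protein_id}")


@dataclass
class PanProteome:
    """The redundant dataset: every record from every genome, in file order."""

    records: list[ProteinRecord] = field(default_factory=list)
    genome_ids: list[str] = field(default_factory=list)

    def add_genome(self, genome_id: str, records: Iterable[ProteinRecord]) -> None:
        if genome_id in self.genome_ids:
            raise ValueError(f"genome {genome_id} already ingested")
        self.genome_ids.append(genome_id)
        self.records.extend(records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class NonRedundantSet:
    """Unique accession IDs with sequence, genome spread and copy totals."""

    # protein_id -> (sequence, occurrence_count, total_copies)
    entries: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def sequence(self, protein_id: str) -> str:
        return self.entries[protein_id][0]

    def occurrence_count(self, protein_id: str) -> int:
        return self.entries[protein_id][1]

    def total_copies(self, protein_id: str) -> int:
        return self.entries[protein_id][2]


def read_proteome_fasta(path: str | Path, genome_id: str | None = None) -> list[ProteinRecord]:
    """Read one genome's protein FASTA (.faa).

    The protein ID is the first whitespace-delimited token of each header.
    Record order is preserved; duplicate IDs within the file are kept (they
    count as extra copies downstream).  An empty file yields an empty list
    with a warning.
    """
    path = Path(path)
    gid = genome_id if genome_id is not None else path.stem.removesuffix("_protein")
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        records.append(ProteinRecord(protein_id=entry.id, genome_id=gid, sequence=seq))
    if not records:
        logger.warning("no FASTA records found in %s", path)
    return records


def load_pan_proteome(faa_paths: Iterable[str | Path]) -> PanProteome:
    """Merge per-genome .faa files into a redundant pan-proteome.

    Genome IDs are taken from file stems; input order defines genome order.
    """
    pan = PanProteome()
    for path in faa_paths:
        path = Path(path)
        gid = path.stem.removesuffix("_protein")
        pan.add_genome(gid, read_proteome_fasta(path, genome_id=gid))
    return pan


def build_nonredundant(pan: PanProteome) -> NonRedundantSet:
    """Collapse the redundant dataset to unique accession IDs.

    occurrence_count = number of distinct genomes carrying the ID;
    total_copies = number of R-D records carrying it.  Identity is ID-based:
    the same ID with two different sequences marks corrupt input and raises.
    """
    if len(pan) == 0:
        raise ValueError("empty pan-proteome")
    seqs: dict[str, str] = {}
    genomes_seen: dict[str, set[str]] = {}
    copies: dict[str, int] = {}
    conflicts: set[str] = set()
    for rec in pan.records:
        prev = seqs.get(rec.protein_id)
        if prev is None:
            seqs[rec.protein_id] = rec.sequence
            genomes_seen[rec.protein_id] = {rec.genome_id}
            copies[rec.protein_id] = 1
        else:
            if prev != rec.sequence:
                conflicts.add(rec.protein_id)
            genomes_seen[rec.protein_id].add(rec.genome_id)
            copies[rec.protein_id] += 1
    if conflicts:
        raise ValueError(
            "conflicting sequences for identical protein IDs: "
            + ", ".join(sorted(conflicts)[:10])
            + ("..." if len(conflicts) > 10 else "")
        )
    nr = NonRedundantSet()
    for pid, seq in seqs.items():
        nr.entries[pid] = (seq, len(genomes_seen[pid]), copies[pid])
    return nr


def spread_report(
    nr: NonRedundantSet, n_genomes: int, cutoff: float = 0.5
) -> pd.DataFrame:
    """Proteins present in at least ``cutoff`` of the genomes.

    Returns a table (protein_id, occurrence_count, percentage) sorted by
    descending percentage; percentage = 100 * count / n_genomes rounded to
    two decimals, the reporting convention used for genome spread tables.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    rows = [
        (pid, count, round(100.0 * count / n_genomes, 2))
        for pid, (_, count, _) in nr.entries.items()
        if count / n_genomes >= cutoff
    ]
    df = pd.DataFrame(rows, columns=["protein_id", "occurrence_count", "percentage"])
    return df.sort_values(
        ["percentage", "protein_id"], ascending=[False, True], ignore_index=True
    )


def composition_stats(records: Iterable[ProteinRecord], ddof: int = 0) -> pd.DataFrame:
    """Per-genome amino-acid composition summary.

    For each protein the residue composition is expressed in percent (summing
    to 100 over the residues present); the genome-level row reports, per amino
    acid, the mean and the variance of that percentage across the genome's
    proteins.  Variance is population variance by default (``ddof=0``).
    """
    records = list(records)
    if not records:
        raise ValueError("genome contains no proteins")
    alphabet = sorted(VALID_RESIDUES)
    comp = pd.DataFrame(
        [
            {aa: 100.0 * rec.sequence.count(aa) / len(rec.sequence) for aa in alphabet}
            for rec in records
        ]
    )
    mean = comp.mean()
    var = comp.var(ddof=ddof) if len(comp) > 1 else comp.iloc[0] * 0.0
    out = pd.DataFrame({"mean_pct": mean, "variance": var})
    out.index.name = "amino_acid"
    return out


def read_annotation_tsv(path: str | Path) -> dict[str, str]:
    """Load a protein_id -> KO table (2-column TSV; blank KO = unannotated)."""
    ann: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            pid = parts[0]
            if pid == "protein_id":  # optional header row
                continue
            ko = parts[1].strip() if len(parts) > 1 else ""
            if ko and not KO_PATTERN.match(ko):
                raise ValueError(f"malformed KO code {ko!r} for {pid}")
            ann[pid] = ko
    return ann


def partition_annotated(
    nr: NonRedundantSet, annotation: Mapping[str, str]
) -> tuple[set[str], set[str]]:
    """Split NR-D IDs into (annotated, unannotated NR-U-D).

    IDs absent from the annotation map, or mapped to blank, are unannotated.
    """
    annotated = {
        pid for pid in nr.entries if annotation.get(pid, "") not in ("", None)
    }
    unannotated = set(nr.entries) - annotated
    return annotated, unannotated


def write_nonredundant(nr: NonRedundantSet, fasta_path: str | Path, tsv_path: str | Path) -> None:
    """Persist NR-D as FASTA plus an occurrence TSV (sorted by ID)."""
    with open(fasta_path, "w") as fa:
        for pid in sorted(nr.entries):
            fa.write(f">{pid}\n{nr.sequence(pid)}\n")
    with open(tsv_path, "w") as tsv:
        tsv.write("protein_id\toccurrence_count\ttotal_copies\n")
        for pid in sorted(nr.entries):
            _, occ, cop = nr.entries[pid]
            tsv.write(f"{pid}\t{occ}\t{cop}\n")
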