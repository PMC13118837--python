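"""Cluster conservation scoring, copy-number profiles and genomic binning.

A cluster is conserved when its member proteins occur in more than 75% of
the analyzed genomes (strict inequality).  Presence counts a genome once no
matter how many copies it holds; repeated occurrences within a genome feed
the copy-number profile instead (e.g. "duplicated in 37 strains,
triplicated in 2").  Cluster gene start positions are aggregated into fixed
50-kb genomic intervals to expose the core-versus-arm positional bias of
conserved clusters along the linear chromosome.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .cluster import ClusterSet
from .proteome import PanProteome


@dataclass
class OccurrenceMatrix:
    """(cluster_id, genome_id) -> copy count, dense over the genome list."""

    counts: dict[int, dict[str, int]]
    genome_ids: list[str]

    def copies(self, cluster_id: int, genome_id: str) -> int:
        return self.counts.get(cluster_id, {}).get(genome_id, 0)


@dataclass
class ConservationRecord:
    cluster_id: int
    presence_fraction: float
    n_present: int
    copy_profile: dict[int, int] = field(default_factory=dict)  # copies -> n strains


def count_occurrences(clusters: ClusterSet, pan: PanProteome) -> OccurrenceMatrix:
    """Copy counts of each cluster in each genome.

    A genome's count is the number of its proteome records whose ID belongs
    to the cluster — repeated records (shared-accession paralogs) included.
    """
    member_of = clusters.member_to_cluster()
    counts: dict[int, dict[str, int]] = {c.cluster_id: {} for c in clusters.clusters}
    for rec in pan.records:
        cid = member_of.get(rec.protein_id)
        if cid is None:
            continue
        per_genome = counts[cid]
        per_genome[rec.genome_id] = per_genome.get(rec.genome_id, 0) + 1
    return OccurrenceMatrix(counts=counts, genome_ids=list(pan.genome_ids))


def filter_conserved(
    matrix: OccurrenceMatrix, cutoff: float = 0.75
) -> list[ConservationRecord]:
    """Clusters present in strictly more than ``cutoff`` of the genomes.

    The >75% rule is a strict inequality: presence in exactly 75% of genomes
    does not qualify.  Each retained record carries the copy-number profile
    (copies -> number of strains with that many copies).
    """
    if not matrix.genome_ids:
        raise ValueError("no genomes in occurrence matrix")
    n = len(matrix.genome_ids)
    records: list[ConservationRecord] = []
    for cid in sorted(matrix.counts):
        per_genome = matrix.counts[cid]
        present = sum(1 for v in per_genome.values() if v >= 1)
        fraction = present / n
        if fraction > cutoff:
            profile = Counter(v for v in per_genome.values() if v >= 1)
            records.append(
                ConservationRecord(
                    cluster_id=cid,
                    presence_fraction=fraction,
                    n_present=present,
                    copy_profile=dict(sorted(profile.items())),
                )
            )
    return records


def genomic_bins(
    positions: Iterable[int], bin_width: int = 50_000
) -> dict[int, int]:
    """Histogram of 1-based gene start coordinates in fixed-width bins.

    Bin index = floor((start - 1) / bin_width), i.e. bins cover
    [1, bin_width], [bin_width + 1, 2*bin_width], ...  Positions are pooled
    across genomes without length normalization.
    """
    histogram: Counter[int] = Counter()
    for start in positions:
        if start <= 0:
            raise ValueError(f"non-positive coordinate {start}")
        histogram[(start - 1) // bin_width] += 1
    return dict(sorted(histogram.items()))


def conservation_table(records: Iterable[ConservationRecord]) -> pd.DataFrame:
    rows = [
        {
            "cluster_id": r.cluster_id,
            "n_present": r.n_present,
            "presence_fraction": r.presence_fraction,
            "copy_profile": ";".join(
                f"{c}x{s}" for c, s in r.copy_profile.items()
            ),
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "n_present", "presence_fraction", "copy_profile"],
    )


def write_bin_histogram(
    histogram: Mapping[int, int], path: str | Path, bin_width: int = 50_000
) -> None:
    with open(path, "w") as fh:
        fh.write("bin_start\tbin_end\tcount\n")
        for idx in sorted(histogram):
            fh.write(
                f"{idx * bin_width + 1}\t{(idx + 1) * bin_width}\t{histogram[idx]}\n"
            )
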