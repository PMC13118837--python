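"""Gene-neighborhood (synteny) analysis around conserved orphan clusters.

For every occurrence of a cluster member gene, an 11-gene synteny window is
built: the center gene plus up to five upstream and five downstream genes in
chromosomal gene order (windows truncate at chromosome ends).  Neighbor
protein IDs are substituted with their KO annotations; a KO is a conserved
syntenic neighbor of a cluster when it appears in a window in strictly more
than 75% of the genomes that carry the cluster (with coordinates).  Clusters
with at least one conserved KO neighbor form the final syntenic cluster
list.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

_ATTR_RE = re.compile(r"\[(\w+)=([^\]]*)\]")
_SPAN_RE = re.compile(r"[<>]?(\d+)\.\.[<>]?(\d+)")


@dataclass(frozen=True)
class GeneLocus:
    genome_id: str
    chromosome_id: str
    protein_id: str
    start: int
    end: int
    strand: str
    compound: bool = False  # join(...) location collapsed to its span

    def sort_key(self) -> tuple[int, int, str]:
        return (self.start, self.end, self.protein_id)


@dataclass
class SyntenyWindow:
    center: GeneLocus
    neighbors: list[GeneLocus]  # gene-order, center excluded, <= 2*flank
    neighbor_kos: list[str] | None = None  # parallel to neighbors after annotation

    def __len__(self) -> int:
        return 1 + len(self.neighbors)


@dataclass
class NeighborConservation:
    cluster_id: int
    n_genomes_with_windows: int
    ko_fraction: dict[str, float] = field(default_factory=dict)
    conserved_kos: list[str] = field(default_factory=list)


def _parse_location(loc: str) -> tuple[int, int, str, bool] | None:
    """Parse an NCBI CDS location string to (start, end, strand, compound).

    Supports ``start..end``, ``complement(...)`` and ``join(a..b,c..d)``
    (also nested, e.g. ``complement(join(...))``); joins collapse to their
    spanning interval and are flagged compound.
    """
    strand = "-" if "complement(" in loc else "+"
    compound = "join(" in loc
    spans = _SPAN_RE.findall(loc)
    if not spans:
        return None
    starts = [int(s) for s, _ in spans]
    ends = [int(e) for _, e in spans]
    start, end = min(starts), max(ends)
    if start <= 0 or end < start:
        return None
    return start, end, strand, compound


def parse_cds_coordinates(
    cds_fasta_path: str | Path, genome_id: str | None = None
) -> list[GeneLocus]:
    """Extract gene loci from a CDS-from-genomic FASTA.

    Headers must carry ``[protein_id=...]`` and ``[location=...]``
    attributes; records lacking either, or with an unparseable location, are
    skipped with a warning.
    """
    path = Path(cds_fasta_path)
    gid = genome_id if genome_id is not None else path.stem.removesuffix("_cds")
    loci: list[GeneLocus] = []
    skipped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        attrs = dict(_ATTR_RE.findall(rec.description))
        pid = attrs.get("protein_id")
        loc = attrs.get("location")
        if not pid or not loc:
            skipped += 1
            continue
        parsed = _parse_location(loc)
        if parsed is None:
            skipped += 1
            continue
        start, end, strand, compound = parsed
        loci.append(
            GeneLocus(
                genome_id=gid,
                chromosome_id=gid,
                protein_id=pid,
                start=start,
                end=end,
                strand=strand,
                compound=compound,
            )
        )
    if skipped:
        logger.warning("skipped %d CDS records without usable headers in %s",
                       skipped, path)
    return loci


def build_windows(
    loci: Sequence[GeneLocus], center_ids: Iterable[str], flank: int = 5
) -> tuple[list[SyntenyWindow], set[str]]:
    """Synteny windows around every occurrence of the given center IDs.

    ``loci`` may span several chromosomes; each chromosome is ordered by
    (start, end, protein_id) and windows take the up-to-``flank`` preceding
    and following genes in that order, truncating at chromosome ends.  A
    duplicated center yields one window per occurrence.  Returns the windows
    plus the set of requested center IDs that had no coordinates.
    """
    centers = set(center_ids)
    by_chrom: dict[tuple[str, str], list[GeneLocus]] = {}
    for locus in loci:
        by_chrom.setdefault((locus.genome_id, locus.chromosome_id), []).append(locus)
    windows: list[SyntenyWindow] = []
    found: set[str] = set()
    for key in sorted(by_chrom):
        ordered = sorted(by_chrom[key], key=GeneLocus.sort_key)
        for i, locus in enumerate(ordered):
            if locus.protein_id not in centers:
                continue
            found.add(locus.protein_id)
            neighbors = (
                ordered[max(0, i - flank) : i] + ordered[i + 1 : i + 1 + flank]
            )
            windows.append(SyntenyWindow(center=locus, neighbors=neighbors))
    return windows, centers - found


def annotate_windows(
    windows: Iterable[SyntenyWindow], annotation: Mapping[str, str]
) -> list[SyntenyWindow]:
    """Attach KO codes to window neighbors (blank where unannotated)."""
    out = []
    for w in windows:
        w.neighbor_kos = [annotation.get(n.protein_id, "") for n in w.neighbors]
        out.append(w)
    return out


def neighbor_conservation(
    cluster_id: int,
    windows: Sequence[SyntenyWindow],
    cutoff: float = 0.75,
) -> NeighborConservation:
    """Per-KO co-occurrence fractions for one cluster's annotated windows.

    The denominator is the number of genomes carrying a cluster member with
    coordinates; a genome contributes once per KO no matter how many of its
    windows contain it (any-window rule).  A KO is conserved iff its
    fraction strictly exceeds ``cutoff``.
    """
    if not windows:
        raise ValueError(f"cluster {cluster_id} has no windows")
    kos_by_genome: dict[str, set[str]] = {}
    for w in windows:
        if w.neighbor_kos is None:
            raise ValueError("windows must be annotated first")
        bag = kos_by_genome.setdefault(w.center.genome_id, set())
        bag.update(ko for ko in w.neighbor_kos if ko)
    n_genomes = len(kos_by_genome)
    counts: dict[str, int] = {}
    for kos in kos_by_genome.values():
        for ko in kos:
            counts[ko] = counts.get(ko, 0) + 1
    fractions = {ko: c / n_genomes for ko, c in sorted(counts.items())}
    conserved = [ko for ko, f in fractions.items() if f > cutoff]
    return NeighborConservation(
        cluster_id=cluster_id,
        n_genomes_with_windows=n_genomes,
        ko_fraction=fractions,
        conserved_kos=conserved,
    )


def select_syntenic_clusters(
    records: Iterable[NeighborConservation],
) -> dict[int, list[str]]:
    """Final syntenic cluster list: clusters with >=1 conserved KO neighbor.

    Returns cluster_id -> sorted conserved KO set; clusters whose every KO
    fraction sits at or below the cutoff are excluded (the conserved-cluster
    vs conserved-with-syntenic-annotation split).
    """
    return {
        r.cluster_id: sorted(r.conserved_kos)
        for r in records
        if r.conserved_kos
    }


def write_windows_tsv(
    windows: Iterable[SyntenyWindow],
    path: str | Path,
    cluster_of: Mapping[str, int] | None = None,
    flank: int = 5,
) -> None:
    """One row per window: genome, chromosome, center, then 2*flank neighbor
    slots with (protein_id, KO, start, end, strand) each."""
    with open(path, "w") as fh:
        head = ["genome_id", "chromosome_id", "cluster_id", "center_protein_id",
                "center_start", "center_end", "center_strand"]
        for i in range(2 * flank):
            head += [f"n{i}_protein_id", f"n{i}_ko", f"n{i}_start",
                     f"n{i}_end", f"n{i}_strand"]
        fh.write("\t".join(head) + "\n")
        for w in windows:
            cid = (
                str(cluster_of.get(w.center.protein_id, ""))
                if cluster_of
                else ""
            )
            row = [w.center.genome_id, w.center.chromosome_id, cid,
                   w.center.protein_id, str(w.center.start),
                   str(w.center.end), w.center.strand]
            kos = w.neighbor_kos or [""] * len(w.neighbors)
            for n, ko in zip(w.neighbors, kos):
                row += [n.protein_id, ko, str(n.start), str(n.end), n.strand]
            row += [""] * (5 * (2 * flank - len(w.neighbors)))
            fh.write("\t".join(row) + "\n")


def write_neighbor_conservation_tsv(
    records: Iterable[NeighborConservation], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tko\tfraction\tconserved\n")
        for r in records:
            for ko, f in r.ko_fraction.items():
                fh.write(
                    f"{r.cluster_id}\t{ko}\t{f:.6f}\t"
                    f"{int(ko in r.conserved_kos)}\n"
                )
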