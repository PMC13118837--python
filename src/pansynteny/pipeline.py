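"""End-to-end pipeline orchestration with resumable TSV intermediates.

Stages run in dependency order::

    ingest -> cluster -> conserve -> synteny -> enrich [-> transfer]

Every stage reads its inputs from disk and writes plain TSV/FASTA outputs to
the output directory, so any stage is independently inspectable and a rerun
can resume from existing outputs (stages whose outputs already exist are
skipped unless forced).  All randomness flows from the single config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from . import cluster as clustering
from . import conservation as conserve_mod
from . import enrichment as enrich_mod
from . import proteome as proteome_mod
from . import synteny as synteny_mod
from . import transfer as transfer_mod

logger = logging.getLogger(__name__)

STAGE_ORDER = ["ingest", "cluster", "conserve", "synteny", "enrich", "transfer"]
STAGE_DEPS = {
    "ingest": [],
    "cluster": ["ingest"],
    "conserve": ["cluster"],
    "synteny": ["conserve"],
    "enrich": ["synteny"],
    "transfer": ["synteny"],
}


class DependencyError(RuntimeError):
    """A stage was requested before its upstream outputs exist."""


@dataclass
class PipelineConfig:
    proteome_dir: str = "."
    cds_dir: str | None = None  # defaults to proteome_dir
    annotation_tsv: str = "annotations.tsv"
    ko_pathway_tsv: str = "ko_pathway.tsv"
    cog_tsv: str | None = None
    reference_genome: str | None = None  # defaults to first genome
    out_dir: str = "pansynteny_out"
    conservation_cutoff: float = 0.75
    neighbor_cutoff: float = 0.75
    spread_cutoff: float = 0.5
    cluster_identity: float = 0.8
    transfer_id_cutoff: float = 0.7
    transfer_cov_cutoff: float = 0.7
    flank: int = 5
    bin_width: int = 50_000
    seed: int = 0
    transfer_targets: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("conservation_cutoff", "neighbor_cutoff", "spread_cutoff",
                     "cluster_identity", "transfer_id_cutoff",
                     "transfer_cov_cutoff"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.flank < 1:
            raise ValueError("flank must be >= 1")
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        if self.cds_dir is None:
            self.cds_dir = self.proteome_dir

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    # ---- file layout helpers ----
    def out(self, name: str) -> Path:
        return Path(self.out_dir) / name

    def faa_paths(self) -> list[Path]:
        return sorted(Path(self.proteome_dir).glob("*.faa"))

    def cds_path(self, genome_id: str) -> Path:
        return Path(self.cds_dir) / f"{genome_id}_cds.fna"


STAGE_OUTPUTS = {
    "ingest": ["genomes.tsv", "nrd.faa", "nrd_occurrence.tsv",
               "spread_report.tsv", "composition.tsv"],
    "cluster": ["clusters.tsv", "ranksize_fit.json"],
    "conserve": ["conserved_clusters.tsv", "bin_histogram.tsv"],
    "synteny": ["windows.tsv", "neighbor_conservation.tsv",
                "syntenic_clusters.tsv"],
    "enrich": ["enrichment_aggregate.tsv", "enrichment_per_cluster.tsv"],
    "transfer": ["transfer.tsv"],
}


def _load_pan(config: PipelineConfig) -> proteome_mod.PanProteome:
    paths = config.faa_paths()
    if not paths:
        raise FileNotFoundError(f"no .faa files in {config.proteome_dir}")
    # CDS companions are not proteomes
    paths = [p for p in paths if not p.stem.endswith("_cds")]
    return proteome_mod.load_pan_proteome(paths)


def stage_ingest(config: PipelineConfig) -> None:
    pan = _load_pan(config)
    nr = proteome_mod.build_nonredundant(pan)
    with open(config.out("genomes.tsv"), "w") as fh:
        fh.write("genome_id\tn_records\n")
        counts: dict[str, int] = {}
        for rec in pan.records:
            counts[rec.genome_id] = counts.get(rec.genome_id, 0) + 1
        for gid in pan.genome_ids:
            fh.write(f"{gid}\t{counts.get(gid, 0)}\n")
    proteome_mod.write_nonredundant(
        nr, config.out("nrd.faa"), config.out("nrd_occurrence.tsv")
    )
    spread = proteome_mod.spread_report(
        nr, len(pan.genome_ids), cutoff=config.spread_cutoff
    )
    spread.to_csv(config.out("spread_report.tsv"), sep="\t", index=False)
    comp_rows = []
    for gid in pan.genome_ids:
        stats = proteome_mod.composition_stats(
            [r for r in pan.records if r.genome_id == gid]
        )
        for aa, row in stats.iterrows():
            comp_rows.append(
                f"{gid}\t{aa}\t{row['mean_pct']:.6f}\t{row['variance']:.6f}"
            )
    with open(config.out("composition.tsv"), "w") as fh:
        fh.write("genome_id\tamino_acid\tmean_pct\tvariance\n")
        fh.write("\n".join(comp_rows) + "\n")


def stage_cluster(config: PipelineConfig) -> None:
    pan = _load_pan(config)
    nr = proteome_mod.build_nonredundant(pan)
    annotation = proteome_mod.read_annotation_tsv(config.annotation_tsv)
    _, unannotated = proteome_mod.partition_annotated(nr, annotation)
    sequences = {pid: nr.sequence(pid) for pid in unannotated}
    cs = clustering.greedy_cluster(sequences, config.cluster_identity)
    multi = clustering.drop_singletons(cs)
    clustering.write_clusters_tsv(multi, config.out("clusters.tsv"))
    sizes = cs.sizes()
    if len(set(sizes)) >= 4:
        fit = clustering.fit_rank_size(sizes)
    else:
        fit = {"note": "fewer than 4 distinct cluster sizes; fit skipped"}
    with open(config.out("ranksize_fit.json"), "w") as fh:
        json.dump(fit, fh, indent=1, sort_keys=True)


def stage_conserve(config: PipelineConfig) -> None:
    pan = _load_pan(config)
    cs = clustering.read_clusters_tsv(config.out("clusters.tsv"))
    matrix = conserve_mod.count_occurrences(cs, pan)
    records = conserve_mod.filter_conserved(matrix, config.conservation_cutoff)
    table = conserve_mod.conservation_table(records)
    table.to_csv(config.out("conserved_clusters.tsv"), sep="\t", index=False)
    member_of = cs.member_to_cluster()
    conserved_ids = {r.cluster_id for r in records}
    starts: list[int] = []
    for gid in pan.genome_ids:
        cds = config.cds_path(gid)
        if not cds.exists():
            logger.warning("no CDS file for %s; skipped in binning", gid)
            continue
        for locus in synteny_mod.parse_cds_coordinates(cds, genome_id=gid):
            if member_of.get(locus.protein_id) in conserved_ids:
                starts.append(locus.start)
    histogram = conserve_mod.genomic_bins(starts, config.bin_width)
    conserve_mod.write_bin_histogram(
        histogram, config.out("bin_histogram.tsv"), config.bin_width
    )


def stage_synteny(config: PipelineConfig) -> None:
    pan_genomes = [p.stem for p in config.faa_paths()
                   if not p.stem.endswith("_cds")]
    cs = clustering.read_clusters_tsv(config.out("clusters.tsv"))
    import pandas as pd

    conserved = pd.read_csv(config.out("conserved_clusters.tsv"), sep="\t")
    conserved_ids = set(conserved["cluster_id"])
    member_of = {
        pid: cid for pid, cid in cs.member_to_cluster().items()
        if cid in conserved_ids
    }
    annotation = proteome_mod.read_annotation_tsv(config.annotation_tsv)
    loci: list[synteny_mod.GeneLocus] = []
    for gid in pan_genomes:
        cds = config.cds_path(gid)
        if cds.exists():
            loci.extend(synteny_mod.parse_cds_coordinates(cds, genome_id=gid))
    windows, missing = synteny_mod.build_windows(
        loci, set(member_of), flank=config.flank
    )
    if missing:
        logger.warning("%d cluster members had no coordinates", len(missing))
    synteny_mod.annotate_windows(windows, annotation)
    by_cluster: dict[int, list[synteny_mod.SyntenyWindow]] = {}
    for w in windows:
        by_cluster.setdefault(member_of[w.center.protein_id], []).append(w)
    records = [
        synteny_mod.neighbor_conservation(cid, ws, cutoff=config.neighbor_cutoff)
        for cid, ws in sorted(by_cluster.items())
    ]
    synteny_mod.write_windows_tsv(
        windows, config.out("windows.tsv"), cluster_of=member_of,
        flank=config.flank,
    )
    synteny_mod.write_neighbor_conservation_tsv(
        records, config.out("neighbor_conservation.tsv")
    )
    selected = synteny_mod.select_syntenic_clusters(records)
    with open(config.out("syntenic_clusters.tsv"), "w") as fh:
        fh.write("cluster_id\tconserved_kos\n")
        for cid in sorted(selected):
            fh.write(f"{cid}\t{','.join(selected[cid])}\n")


def _read_syntenic(config: PipelineConfig) -> dict[int, list[str]]:
    selected: dict[int, list[str]] = {}
    with open(config.out("syntenic_clusters.tsv")) as fh:
        fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 2 and parts[0]:
                selected[int(parts[0])] = [k for k in parts[1].split(",") if k]
    return selected


def _reference_population(config: PipelineConfig) -> list[str]:
    """KO entries of the reference genome's annotated proteins."""
    paths = [p for p in config.faa_paths() if not p.stem.endswith("_cds")]
    ref = config.reference_genome or paths[0].stem
    ref_path = Path(config.proteome_dir) / f"{ref}.faa"
    annotation = proteome_mod.read_annotation_tsv(config.annotation_tsv)
    population = []
    for rec in proteome_mod.read_proteome_fasta(ref_path, genome_id=ref):
        ko = annotation.get(rec.protein_id, "")
        if ko:
            population.append(ko)
    return population


def stage_enrich(config: PipelineConfig) -> None:
    selected = _read_syntenic(config)
    category_map = enrich_mod.read_category_map(config.ko_pathway_tsv)
    population = _reference_population(config)
    observed_union = sorted({ko for kos in selected.values() for ko in kos})
    agg = enrich_mod.enrich(observed_union, population, category_map,
                            mode="aggregate")
    agg.to_csv(config.out("enrichment_aggregate.tsv"), sep="\t", index=False,
               float_format="%.6g")
    per = enrich_mod.enrich(
        {cid: kos for cid, kos in selected.items()},
        population, category_map, mode="per_cluster",
    )
    per.to_csv(config.out("enrichment_per_cluster.tsv"), sep="\t", index=False,
               float_format="%.6g")


def stage_transfer(config: PipelineConfig) -> None:
    if not config.transfer_targets:
        config.out("transfer.tsv").write_text(
            "cluster_id\tn_queries\tn_conserved\tconserved_pct\t"
            "synteny_checked\tmatched_expected_kos\n"
        )
        return
    selected = _read_syntenic(config)
    cs = clustering.read_clusters_tsv(config.out("clusters.tsv"))
    nr_seqs = {
        rec.protein_id: rec.sequence
        for rec in proteome_mod.read_proteome_fasta(
            config.out("nrd.faa"), genome_id="nrd"
        )
    }
    cluster_members = {
        c.cluster_id: {pid: nr_seqs[pid] for pid in c.member_ids}
        for c in cs.clusters
        if c.cluster_id in selected
    }
    annotation = proteome_mod.read_annotation_tsv(config.annotation_tsv)
    all_results = []
    for target in config.transfer_targets:
        target_path = Path(target)
        target_id = target_path.stem
        target_proteome = {
            rec.protein_id: rec.sequence
            for rec in proteome_mod.read_proteome_fasta(
                target_path, genome_id=target_id
            )
        }
        cds = target_path.with_name(f"{target_id}_cds.fna")
        target_loci = (
            synteny_mod.parse_cds_coordinates(cds, genome_id=target_id)
            if cds.exists()
            else None
        )
        results = transfer_mod.cluster_transfer(
            cluster_members,
            target_proteome,
            expected_kos=selected,
            target_annotation=annotation if target_loci else None,
            target_loci=target_loci,
            id_cutoff=config.transfer_id_cutoff,
            cov_cutoff=config.transfer_cov_cutoff,
            flank=config.flank,
        )
        for r in results:
            all_results.append((target_id, r))
    with open(config.out("transfer.tsv"), "w") as fh:
        fh.write(
            "target\tcluster_id\tn_queries\tn_conserved\tconserved_pct\t"
            "synteny_checked\tmatched_expected_kos\n"
        )
        for target_id, r in all_results:
            fh.write(
                f"{target_id}\t{r.cluster_id}\t{r.n_queries}\t{r.n_conserved}"
                f"\t{r.conserved_pct}\t{int(r.synteny_checked)}\t"
                f"{','.join(r.matched_expected_kos)}\n"
            )


_STAGE_FN = {
    "ingest": stage_ingest,
    "cluster": stage_cluster,
    "conserve": stage_conserve,
    "synteny": stage_synteny,
    "enrich": stage_enrich,
    "transfer": stage_transfer,
}


def _outputs_exist(config: PipelineConfig, stage: str) -> bool:
    return all(config.out(name).exists() for name in STAGE_OUTPUTS[stage])


def run(
    config: PipelineConfig,
    stages: list[str] | None = None,
    force: bool = False,
) -> dict[str, list[str]]:
    """Run the requested stages in dependency order.

    Stages whose outputs already exist are skipped unless ``force``.  A
    stage whose upstream outputs are missing raises DependencyError naming
    the stage.  Returns a manifest stage -> output paths.
    """
    requested = stages if stages is not None else STAGE_ORDER[:-1]
    unknown = set(requested) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    Path(config.out_dir).mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[str]] = {}
    for stage in STAGE_ORDER:
        if stage not in requested:
            continue
        for dep in STAGE_DEPS[stage]:
            if not _outputs_exist(config, dep):
                raise DependencyError(
                    f"stage '{stage}' requires outputs of '{dep}' which are "
                    "missing; run it first"
                )
        if _outputs_exist(config, stage) and not force:
            logger.info("stage %s up to date; skipped", stage)
        else:
            logger.info("running stage %s", stage)
            _STAGE_FN[stage](config)
        manifest[stage] = [str(config.out(n)) for n in STAGE_OUTPUTS[stage]]
    with open(config.out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
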