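"""Synthetic multi-genome pangenome generator with planted ground truth.

Emulates a collection of complete actinomycete-like genomes, each a single
linear chromosome of protein-coding genes, with the features the downstream
pipeline keys on:

* **Orphan families** — groups of homologous unannotated proteins planted at
  controlled conservation fractions.  Presence is allocated by exact count
  (a seeded shuffle picks ``round(c * n_genomes)`` carrier genomes), so a
  planted conservation fraction is exactly recoverable, not merely expected.
* **Core/arm positional bias** — the chromosome has a central core region
  (``core_fraction`` of the gene order) where orphan families are anchored,
  flanked by two variable arms, mirroring the linear-chromosome architecture
  of *Streptomyces*.
* **Planted syntenic neighbors** — each family carries a set of annotated
  neighbor genes with fixed mock KO codes.  In a controlled fraction of
  carrier genomes (``neighbor_preservation``, again allocated by exact
  count) those genes sit within the 5-gene flank of the family member;
  otherwise they are relocated to the left chromosomal arm.
* **Gene duplication** — with probability ``duplication_rate`` a carrier
  genome holds a second copy of the family gene (same accession, as for
  NCBI multispecies records), placed in the right arm.
* **Shared identical proteins** — a few ubiquitous proteins with identical
  accession and sequence across a controlled fraction of genomes, feeding
  the non-redundant-dataset spread report.

Per genome the generator writes a protein FASTA (``<genome>.faa``) and a
CDS nucleotide FASTA (``<genome>_cds.fna``) whose headers carry
``[protein_id=...]`` and ``[location=...]`` attributes in the NCBI
CDS-from-genomic dialect.  Collection-level tables are a protein->KO
annotation TSV, a KO->pathway membership TSV and a protein->COG-category
TSV.  The complete ground truth is written to ``truth.json``.

Identical configuration and seed give byte-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .align import AMINO_ACIDS

# one codon per amino acid; CDS content is an exact back-translation and is
# a placeholder — only headers and coordinates matter downstream
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
    "X": "NNN",
}

_NEIGHBOR_OFFSETS = (-2, 1, 3)  # planted KO genes, relative to the family anchor
_KOS_PER_FAMILY = len(_NEIGHBOR_OFFSETS)
_INTERGENIC_GAP = 50  # bp between consecutive CDS
_ORPHAN_COG_CYCLE = "SSKIT"  # mostly function-unknown, as for real orphan sets
_BACKGROUND_COGS = "CEFGHJLMNOPQUV"


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class SimConfig:
    """Study conditions for one synthetic pangenome.

    Defaults describe a 25-genome collection of ~400-gene chromosomes with
    20 planted orphan families: ten fully conserved with tightly preserved
    neighborhoods, five at 50% conservation, and five fully conserved but
    with largely shuffled neighborhoods.
    """

    n_genomes: int = 25
    genes_per_genome: int = 400
    core_fraction: float = 0.5
    n_orphan_families: int = 20
    family_conservation: Sequence[float] = field(
        default_factory=lambda: [1.0] * 10 + [0.5] * 5 + [1.0] * 5
    )
    neighbor_preservation: Sequence[float] | float = field(
        default_factory=lambda: [0.95] * 10 + [0.95] * 5 + [0.3] * 5
    )
    duplication_rate: float = 0.1
    identity_within_family: float = 0.95
    protein_length_range: tuple[int, int] = (80, 260)
    shared_spread: Sequence[float] = (1.0, 0.9, 0.6, 0.52)
    seed: int = 0

    def neighbor_preservation_list(self) -> list[float]:
        if isinstance(self.neighbor_preservation, (int, float)):
            return [float(self.neighbor_preservation)] * self.n_orphan_families
        return [float(p) for p in self.neighbor_preservation]

    def validate(self) -> None:
        if self.n_genomes < 2:
            raise ConfigError("n_genomes must be >= 2")
        if self.genes_per_genome < 20:
            raise ConfigError("genes_per_genome must be >= 20")
        if not 0.0 < self.core_fraction <= 1.0:
            raise ConfigError("core_fraction must be in (0, 1]")
        if self.n_orphan_families < 1:
            raise ConfigError("n_orphan_families must be >= 1")
        if len(self.family_conservation) != self.n_orphan_families:
            raise ConfigError(
                "family_conservation length must equal n_orphan_families"
            )
        for c in self.family_conservation:
            if not 0.0 <= c <= 1.0:
                raise ConfigError("family_conservation values must be in [0, 1]")
        for p in self.neighbor_preservation_list():
            if not 0.0 <= p <= 1.0:
                raise ConfigError("neighbor_preservation values must be in [0, 1]")
        if not 0.0 <= self.duplication_rate <= 1.0:
            raise ConfigError("duplication_rate must be in [0, 1]")
        if not 0.0 < self.identity_within_family <= 1.0:
            raise ConfigError("identity_within_family must be in (0, 1]")
        lo, hi = self.protein_length_range
        if lo < 14 or hi < lo:
            raise ConfigError(
                "protein_length_range must satisfy 14 <= min <= max"
            )
        for s in self.shared_spread:
            if not 0.0 <= s <= 1.0:
                raise ConfigError("shared_spread values must be in [0, 1]")
        # chromosome layout feasibility
        L = self.genes_per_genome
        core_len = round_half_up(self.core_fraction * L)
        core_start = (L - core_len) // 2
        n_fam = self.n_orphan_families
        if core_len < 7 * n_fam:
            raise ConfigError(
                "genes_per_genome too small: core region cannot space "
                f"{n_fam} families at >=7 gene intervals"
            )
        if core_start < _KOS_PER_FAMILY * n_fam + 8:
            raise ConfigError(
                "genes_per_genome too small: left arm cannot host relocated "
                "neighbor genes"
            )
        right_len = L - core_start - core_len
        if right_len < 2 * n_fam + 3 * len(self.shared_spread) + 6:
            raise ConfigError(
                "genes_per_genome too small: right arm cannot host duplicates "
                "and shared proteins"
            )


@dataclass
class GroundTruth:
    """Planted structure of a simulated pangenome (the manifest)."""

    genome_ids: list[str]
    genes_per_genome: dict[str, int]
    families: list[dict]
    shared_proteins: list[dict]
    config: dict

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict_safe(self), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)

    def family(self, family_id: str) -> dict:
        for fam in self.families:
            if fam["family_id"] == family_id:
                return fam
        raise KeyError(family_id)


def asdict_safe(truth: GroundTruth) -> dict:
    d = asdict(truth)
    cfg = d["config"]
    for key, val in list(cfg.items()):
        if isinstance(val, tuple):
            cfg[key] = list(val)
    return d


def mutate_protein(seq: str, target_identity: float, seed: int) -> str:
    """Mutate a protein to an exact target identity.

    Exactly ``len(seq) - round(target_identity * len(seq))`` positions
    (chosen by the seeded RNG) are substituted with a different residue, so
    the identity of the result to the input is the rounded target exactly.
    """
    if not seq:
        raise ValueError("cannot mutate empty sequence")
    if not 0.0 <= target_identity <= 1.0:
        raise ValueError("target_identity must be in [0, 1]")
    n = len(seq)
    n_keep = round_half_up(target_identity * n)
    n_mut = n - n_keep
    if n_mut == 0:
        return seq
    rng = np.random.default_rng(seed)
    positions = rng.choice(n, size=n_mut, replace=False)
    out = list(seq)
    for pos in positions:
        choices = [aa for aa in AMINO_ACIDS if aa != out[pos]]
        out[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def _random_protein(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    idx = rng.integers(0, len(AMINO_ACIDS), size=length)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _back_translate(protein: str) -> str:
    return "".join(_CODON[aa] for aa in protein) + "TAA"


def _exact_subset(rng: np.random.Generator, n: int, fraction: float) -> list[int]:
    """Seeded shuffle choosing exactly round(fraction * n) of range(n)."""
    k = round_half_up(fraction * n)
    order = rng.permutation(n)
    return sorted(int(i) for i in order[:k])


def simulate_pangenome(config: SimConfig, out_dir: str | Path) -> GroundTruth:
    """Write a synthetic pangenome file set and return its ground truth.

    Emits per genome ``<genome>.faa`` and ``<genome>_cds.fna``, plus
    ``annotations.tsv`` (protein_id -> KO, all non-orphan genes),
    ``ko_pathway.tsv`` (KO -> pathway membership), ``cog.tsv``
    (protein_id -> COG category) and ``truth.json``.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(config.seed)
    L = config.genes_per_genome
    n = config.n_genomes
    n_fam = config.n_orphan_families
    core_len = round_half_up(config.core_fraction * L)
    core_start = (L - core_len) // 2
    right_start = core_start + core_len
    genome_ids = [f"GENOME{g:03d}" for g in range(n)]
    preservation = config.neighbor_preservation_list()
    lo, hi = config.protein_length_range

    # ---- plan the planted structure (all RNG draws in fixed order) ----
    fam_base = [_random_protein(rng, lo, hi) for _ in range(n_fam)]
    fam_carriers = [
        _exact_subset(rng, n, c) for c in config.family_conservation
    ]
    fam_preserved = []
    for f in range(n_fam):
        carriers = fam_carriers[f]
        picked = _exact_subset(rng, len(carriers), preservation[f])
        fam_preserved.append(sorted(carriers[i] for i in picked))
    fam_duplicated = [
        sorted(g for g in fam_carriers[f] if rng.random() < config.duplication_rate)
        for f in range(n_fam)
    ]
    fam_member_seq: list[dict[int, str]] = []
    for f in range(n_fam):
        seqs: dict[int, str] = {}
        founder = fam_carriers[f][0] if fam_carriers[f] else None
        for g in fam_carriers[f]:
            if g == founder:
                seqs[g] = fam_base[f]
            else:
                child_seed = int(rng.integers(0, 2**31 - 1))
                seqs[g] = mutate_protein(
                    fam_base[f], config.identity_within_family, child_seed
                )
        fam_member_seq.append(seqs)
    fam_kos = [
        [f"K9{f:02d}{j:02d}" for j in range(_KOS_PER_FAMILY)] for f in range(n_fam)
    ]
    fam_neighbor_seq = [
        [_random_protein(rng, lo, hi) for _ in range(_KOS_PER_FAMILY)]
        for _ in range(n_fam)
    ]

    n_shared = len(config.shared_spread)
    shared_seq = [_random_protein(rng, lo, hi) for _ in range(n_shared)]
    shared_carriers = [
        _exact_subset(rng, n, s) for s in config.shared_spread
    ]

    anchors = [
        core_start + int((f + 0.5) * core_len / n_fam) for f in range(n_fam)
    ]

    # background KO pool, one per chromosome slot, shared across genomes
    bg_kos = [f"K{10000 + j:05d}" for j in range(L)]

    annotations: dict[str, str] = {}
    cogs: dict[str, str] = {}
    families_truth: list[dict] = [
        {
            "family_id": f"FAM{f:02d}",
            "conservation": float(config.family_conservation[f]),
            "neighbor_preservation": float(preservation[f]),
            "planted_kos": fam_kos[f],
            "carrier_genomes": [genome_ids[g] for g in fam_carriers[f]],
            "preserved_genomes": [genome_ids[g] for g in fam_preserved[f]],
            "duplicated_genomes": [genome_ids[g] for g in fam_duplicated[f]],
            "members": {},   # genome_id -> protein_id
            "positions": {},  # genome_id -> [[start, end], ...] per copy
        }
        for f in range(n_fam)
    ]
    shared_truth = [
        {
            "protein_id": f"WP_SHARED{i:03d}.1",
            "spread": float(config.shared_spread[i]),
            "carrier_genomes": [genome_ids[g] for g in shared_carriers[i]],
            "ko": f"K{1 + i:05d}",
        }
        for i in range(n_shared)
    ]
    genes_per_genome: dict[str, int] = {}

    for g, gid in enumerate(genome_ids):
        grng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 1000 + g])
        )
        slots: list[dict | None] = [None] * L

        def place(slot: int, gene: dict) -> None:
            if slot < 0 or slot >= L or slots[slot] is not None:
                raise ConfigError(
                    "genes_per_genome too small for the planted layout"
                )
            slots[slot] = gene

        for f in range(n_fam):
            if g not in fam_carriers[f]:
                continue
            pid = f"WP_F{f:02d}G{g:03d}.1"
            fam = families_truth[f]
            fam["members"][gid] = pid
            place(
                anchors[f],
                {"pid": pid, "seq": fam_member_seq[f][g], "orphan": True,
                 "family": f, "product": f"hypothetical protein FAM{f:02d}"},
            )
            preserved = g in fam_preserved[f]
            for j, ko in enumerate(fam_kos[f]):
                npid = f"WP_N{f:02d}{j}G{g:03d}.1"
                slot = (
                    anchors[f] + _NEIGHBOR_OFFSETS[j]
                    if preserved
                    else _KOS_PER_FAMILY * f + 2 + j
                )
                place(slot, {"pid": npid, "seq": fam_neighbor_seq[f][j],
                             "orphan": False, "ko": ko,
                             "product": f"planted neighbor {ko}"})
                annotations[npid] = ko
                cogs[npid] = _BACKGROUND_COGS[(f + j) % len(_BACKGROUND_COGS)]
            if g in fam_duplicated[f]:
                place(right_start + 2 * f + 1,
                      {"pid": pid, "seq": fam_member_seq[f][g], "orphan": True,
                       "family": f,
                       "product": f"hypothetical protein FAM{f:02d}"})
            cogs[pid] = _ORPHAN_COG_CYCLE[f % len(_ORPHAN_COG_CYCLE)]

        for i in range(n_shared):
            if g in shared_carriers[i]:
                pid = shared_truth[i]["protein_id"]
                place(L - 1 - 3 * i,
                      {"pid": pid, "seq": shared_seq[i], "orphan": False,
                       "ko": shared_truth[i]["ko"],
                       "product": "ubiquitous conserved protein"})
                annotations[pid] = shared_truth[i]["ko"]
                cogs[pid] = "J"

        # fill remaining slots with genome-specific background genes whose
        # KO comes from the shared pool via a per-genome shuffle
        ko_perm = grng.permutation(L)
        bg_counter = 0
        for slot in range(L):
            if slots[slot] is not None:
                continue
            pid = f"WP_{g:03d}B{bg_counter:04d}.1"
            bg_counter += 1
            seq = _random_protein(grng, lo, hi)
            ko = bg_kos[int(ko_perm[slot])]
            slots[slot] = {"pid": pid, "seq": seq, "orphan": False, "ko": ko,
                           "product": f"annotated protein {ko}"}
            annotations[pid] = ko
            cogs[pid] = _BACKGROUND_COGS[
                int(ko_perm[slot]) % len(_BACKGROUND_COGS)
            ]

        # assign strictly increasing, non-overlapping 1-based coordinates
        cursor = 1
        strands = grng.integers(0, 2, size=L)
        faa_lines: list[str] = []
        fna_lines: list[str] = []
        for slot in range(L):
            gene = slots[slot]
            cds = _back_translate(gene["seq"])
            start, end = cursor, cursor + len(cds) - 1
            cursor = end + 1 + _INTERGENIC_GAP
            loc = (
                f"{start}..{end}"
                if strands[slot] == 0
                else f"complement({start}..{end})"
            )
            faa_lines.append(f">{gene['pid']} {gene['product']} [{gid}]")
            faa_lines.append(gene["seq"])
            fna_lines.append(
                f">lcl|{gid}_cds_{slot:04d} [protein_id={gene['pid']}] "
                f"[location={loc}]"
            )
            fna_lines.append(cds)
            if gene["orphan"]:
                fam = families_truth[gene["family"]]
                fam["positions"].setdefault(gid, []).append([start, end])

        (out_dir / f"{gid}.faa").write_text("\n".join(faa_lines) + "\n")
        (out_dir / f"{gid}_cds.fna").write_text("\n".join(fna_lines) + "\n")
        genes_per_genome[gid] = L

    # ---- collection-level tables ----
    with open(out_dir / "annotations.tsv", "w") as fh:
        fh.write("protein_id\tko\n")
        for pid in sorted(annotations):
            fh.write(f"{pid}\t{annotations[pid]}\n")

    pathways: list[tuple[str, str, str]] = []
    for f in range(n_fam):
        for ko in fam_kos[f]:
            pathways.append((ko, "path_planted", "Planted syntenic pathway"))
    for j, ko in enumerate(bg_kos):
        pathways.append((ko, f"path_bg_{j % 20:02d}", f"Background pathway {j % 20:02d}"))
    for s in shared_truth:
        pathways.append((s["ko"], "path_bg_00", "Background pathway 00"))
    with open(out_dir / "ko_pathway.tsv", "w") as fh:
        fh.write("ko\tpathway_id\tpathway_name\n")
        for ko, pw, name in sorted(pathways):
            fh.write(f"{ko}\t{pw}\t{name}\n")

    with open(out_dir / "cog.tsv", "w") as fh:
        fh.write("protein_id\tcog\n")
        for pid in sorted(cogs):
            fh.write(f"{pid}\t{cogs[pid]}\n")

    truth = GroundTruth(
        genome_ids=genome_ids,
        genes_per_genome=genes_per_genome,
        families=families_truth,
        shared_proteins=shared_truth,
        config={**asdict(config)},
    )
    truth.save(out_dir / "truth.json")
    return truth
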