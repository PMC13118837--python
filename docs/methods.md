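# Methods

## The analysis model

`pansynteny` asks, for each group of homologous unannotated proteins in a
multi-genome collection: *is the group conserved across the genus, and which
annotated genes reliably co-occur in its genomic neighborhood?* The answer
is computed in five stages, each a pure function of plain-text inputs.

**Identity of a protein.** Proteins are identified by their accession ID
(WP_-style), not by sequence. Identical IDs in different genomes are the
same protein; the same ID appearing twice within one genome (a multispecies
accession shared by paralogs) is legal and counts toward *total copies* but
only once toward the *occurrence count* (number of genomes carrying the ID).
An ID carrying two different sequences is treated as corrupt input and
rejected. All genomes must share one ID scheme.

**Conservation.** A cluster is conserved when its members occur in strictly
more than 75% of the analyzed genomes — "more than 75%" is implemented as a
strict inequality, so presence in exactly 3 of 4 genomes does not qualify.
Presence counts each genome once; copy counts feed a separate copy-number
profile (copies → number of strains). The cutoff is configurable.

**Synteny windows.** Windows are defined in gene order (rank), not base-pair
distance: the center gene plus up to five genes on each side of it along the
chromosome, truncating at the ends, so a window holds between 1 and 11 genes
and exactly 11 whenever five genes flank each side. Strand is recorded but
ignored for membership. Compound (`join(...)`) CDS locations collapse to
their spanning interval and are flagged; ordering ties break
deterministically by (start, end, ID). Chromosomes are linear — no
wraparound — matching *Streptomyces* chromosome biology.

**Neighbor conservation.** For each cluster, the fraction of a KO is
(genomes in which at least one window of the cluster contains the KO) /
(genomes carrying a cluster member with coordinates). The denominator is
cluster-carrying genomes, not all genomes, because the neighborhood exists
only where the gene exists; an all-genomes denominator is available. A
genome with several cluster copies contributes once per KO (any-window
rule) to avoid double counting. A KO is conserved at fraction > 0.75
(strict), and a cluster with at least one conserved KO enters the final
syntenic list.

**Enrichment.** For a category (KEGG pathway via a KO→pathway table, or COG
class via a protein→COG table): k = observation-list members in the
category, n = observation-list size, K = category members in the population,
N = population size. The population is the annotated protein set of a single
reference genome supplied as input. Reported per category: FE = (k/n)/(K/N);
the hypergeometric upper tail P(X ≥ k); the odds ratio on the 2×2 table
a=k, b=n−k, c=K−k, d=(N−K)−b; and the Benjamini–Hochberg step-up value
q(i) = min_{j≥i} p(j)·m/j capped at 1. In aggregate mode all categories form
one BH family; in per-cluster mode each cluster's categories are corrected
independently with m = categories tested for that cluster (m is
configurable, since only the independence of the correction is specified by
the procedure, not the family size). A category observed but absent from the
population is reported with an `excluded` flag and never tested — the
systematic version of excluding a pathway missing from the reference genome.
An item belonging to several pathways counts once per pathway.

**Cross-taxa transfer.** blastp is replaced by exact Smith–Waterman local
alignment (BLOSUM62, gap open 10, extend 1): correct at the scale this
package targets and free of heuristic seeding; above 1,000 target sequences
a shared-4-mer prefilter skips hopeless targets. Identity is matches /
aligned columns and coverage is aligned query span / query length ("70%
coverage" is interpreted as *query* coverage; both cutoffs configurable,
both strict `>`). One representative query per cluster (the longest member,
ties by ID) bounds runtime; a full-member mode exists. Conservation
percentage is monotone non-increasing in both cutoffs.

## Clustering choices

Adaptive-threshold clustering tools are replaced by fixed-threshold greedy
centroid clustering because the scientific contribution sits downstream of
clustering and the tests need determinism: sequences are visited by
decreasing length (ties by ID), each joining the first centroid at
global-alignment identity ≥ 0.8 or founding a new cluster. The length-then-ID
visit order makes the result independent of input file order. "Identity" is
matches / alignment columns under global alignment with BLOSUM62, gap open
10, extend 1 — stated explicitly because "similar" is otherwise undefined.
An external clusterer's membership TSV (cluster_id, protein_id) can be
imported in place of the built-in pass. Multiple-alignment-based cluster QC
is replaced by a pairwise-identity coherence check (all pairs, or a seeded
sample of ≤ 200 pairs above 20 members; pass iff the minimum identity
reaches 0.5).

The rank–size curve of cluster sizes (duplicate sizes collapsed once, ranks
1-based on the descending curve) is fitted by least squares with an
exponential decay a·e^(−b·x) and a Hill curve a·x^h/(c^h + x^h) with h
allowed negative so the sigmoid can decrease. R² = 1 − SS_res/SS_tot;
a flat curve (SS_tot = 0) or non-convergence yields R² = NaN with a cleared
`converged` flag rather than an exception.

## The synthetic pangenome generator

The generator emulates the features of a genus-scale proteome collection the
pipeline keys on, with planted, exactly recoverable truth:

- **Exact-count allocation.** Family presence (conservation c) is allocated
  by a seeded shuffle choosing exactly round(c·n_genomes) carrier genomes —
  not independent coin flips — so a planted fraction is testable as an
  equality. Neighborhood preservation is allocated the same way over carrier
  genomes. round() is round-half-up (floor(x+0.5)), so 0.5·25 → 13.
- **Chromosome layout.** Each genome is one linear chromosome of
  `genes_per_genome` gene slots: a central core region (`core_fraction` of
  the gene order) flanked by two arms. Families are anchored at fixed,
  evenly spaced core slots (≥ 7 slots apart, validated) so neighborhoods
  never overlap; in preserved genomes the family's three planted KO genes
  sit at offsets −2, +1, +3 from the anchor, otherwise they are relocated to
  the left arm (far outside any window). Duplicated family copies (same
  accession, probability `duplication_rate` per carrier) go to the right
  arm, as do a few shared identical proteins planted at controlled spreads
  for the NR-D spread report. Background genes fill the remaining slots with
  genome-specific accessions and KOs drawn from a pool shared across genomes
  through a per-genome shuffle, so no background KO is systematically
  adjacent to a family.
- **Sequences.** Each family has a founder sequence carried unmutated by its
  lowest-index genome; other members are mutated from the founder to exactly
  round((1−identity)·length) substitutions (default within-family identity
  0.95, giving a wide margin over the 0.8 clustering threshold even between
  two mutated members, whose expected pairwise identity is ≈ 0.905).
  Coordinates are strictly increasing, non-overlapping, 1-based, with a
  50-bp intergenic gap; CDS records are exact back-translations with a fixed
  codon table — placeholder content, since only headers and coordinates are
  consumed downstream. Mock KO codes follow the K+5-digit shape so real KO
  tables are drop-in compatible.
- **Determinism.** All randomness flows from the single config seed through
  fixed-order draws; identical configuration and seed give byte-identical
  files.

Default study conditions: 25 genomes × 400 genes, 20 orphan families —
ten at conservation 1.0 with neighborhood preservation 0.95, five at
conservation 0.5, five at conservation 1.0 with preservation 0.3 —
duplication rate 0.1, protein lengths 80–260 residues, four shared proteins
at spreads 1.0/0.9/0.6/0.52. These sizes keep a full run in seconds while
leaving every filter a non-trivial decision (the 0.5-conservation families
must fail the >75% rule; the 0.3-preservation families must pass it but fail
the synteny rule).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no nucleotide-level evolution or GC-content
structure, no horizontal transfer, no rearrangements or inversions (gene
order varies only through background shuffling), no quantitative core-to-arm
conservation decay (the core/arm split is a binary placement bias; no
published quantitative model exists for the decay), no annotation noise
(KO tables are complete and correct for all non-orphan genes), and random
background sequences rather than realistically related ones, which makes
inter-family identities far lower than between real paralogous families.
Real clustering problems (domain sharing, promiscuous modules) are therefore
easier here than in nature.

## Numerical choices

- The hypergeometric tail is summed in log space via log-gamma and
  `logsumexp`; it agrees with an exact rational-arithmetic enumeration to
  ≤ 1e-12 over all parameter combinations with N ≤ 12 (checked in the test
  suite and recomputed by the acceptance script) and with
  `scipy.stats.hypergeom.sf` at large N.
- BH q-values are computed by a vectorized reverse cumulative minimum and
  cross-checked against `statsmodels.stats.multitest.multipletests`
  (`fdr_bh`); an explicit m ≥ #p-values is supported for partial families.
- Zero cells in the odds-ratio table get the Haldane–Anscombe +0.5 added to
  all four cells, with a `corrected` flag — the standard finite-OR policy
  when a zero-cell rule is not otherwise specified.
- Amino-acid composition variance is population variance (ddof = 0) by
  default and switchable; percentages are reported to two decimals with the
  total number of genomes as the denominator.
- Genomic binning uses bin index floor((start−1)/50 000) on raw absolute
  coordinates from each chromosome start, pooled across genomes without
  genome-length normalization — a documented limitation when genome lengths
  vary widely.
- Alignment identity always includes gap columns in the denominator; end
  gaps are penalized in global mode.

## Pipeline and reproducibility

Stages (`ingest → cluster → conserve → synteny → enrich [→ transfer]`)
communicate only through plain TSV/FASTA files in the output directory, so
any stage is independently inspectable and rerunnable; stages with existing
outputs are skipped unless forced, and a stage whose upstream outputs are
missing fails with a dependency error naming the stage. Two runs with
identical config and inputs are byte-identical. The `--threads` CLI flag is
accepted for interface stability but stages run single-threaded — at the
problem sizes the package targets, alignment dominates and stays in seconds.

## Known limitations

- ID-based protein identity cannot merge renamed accessions across database
  versions; a genome using a different ID scheme must be converted upstream.
- Greedy centroid clustering is order-stable but threshold-rigid: families
  straddling the identity threshold can split (the chain A–B–C case where C
  matches B but not the centroid A). Adaptive clusterers can be substituted
  via the membership-TSV import.
- The conserved-neighbor denominator choice (cluster-carrying genomes)
  inflates fractions for rare clusters relative to an all-genomes
  denominator; both modes are exposed.
- Aggregate enrichment mixes KO-level observation lists with protein-level
  populations when a KO is multi-copy in the reference; with the single-copy
  reference annotations the generator emits, the two coincide.
- Smith–Waterman transfer is exact but O(len²) per pair; for proteome-scale
  targets the 4-mer prefilter is essential and very distant true homologs
  below ~40% identity may be prefiltered away — irrelevant at the 70%
  transfer threshold.
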