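"""Pairwise protein alignment helpers shared by clustering and cross-taxa transfer.

Identity is defined as matching residues divided by alignment columns
(including gap columns), under BLOSUM62 with gap open 10 and gap extend 1.
Global alignments are used for within-genus homology (clustering, coherence);
local (Smith-Waterman) alignments for cross-taxa best-hit searches.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@lru_cache(maxsize=4)
def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    aligner.mode = mode
    return aligner


def global_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical columns in the optimal global alignment.

    Columns are all alignment positions: matches, mismatches and gaps.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequence")
    alignment = _aligner("global").align(seq_a, seq_b)[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns if columns else 0.0


def quick_identity_bound(seq_a: str, seq_b: str) -> float:
    """Upper bound on global identity from lengths alone.

    Matches cannot exceed the shorter length and columns cannot be fewer
    than the longer length, so identity <= min(len)/max(len).  Used to skip
    alignments that cannot reach a threshold.
    """
    la, lb = len(seq_a), len(seq_b)
    return min(la, lb) / max(la, lb)


def local_alignment(query: str, target: str) -> tuple[float, float, float]:
    """Smith-Waterman local alignment of query vs target.

    Returns ``(score, identity, query_coverage)`` where identity is
    matches / aligned columns within the local alignment and coverage is
    the aligned query span divided by the query length.
    """
    if not query or not target:
        raise ValueError("cannot align empty sequence")
    alignments = _aligner("local").align(query, target)
    if len(alignments) == 0:
        return 0.0, 0.0, 0.0
    alignment = alignments[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    query_blocks = alignment.aligned[0]
    if len(query_blocks) == 0:
        return float(alignment.score), 0.0, 0.0
    span = int(query_blocks[-1][1]) - int(query_blocks[0][0])
    coverage = span / len(query)
    return float(alignment.score), identity, coverage


def kmer_set(seq: str, k: int = 4) -> set[str]:
    """All overlapping k-mers of a sequence (empty set if shorter than k)."""
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}
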