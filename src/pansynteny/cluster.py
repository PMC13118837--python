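"""Greedy centroid clustering of unannotated proteins and cluster-size fits.

Unannotated (orphan) proteins are grouped into homology clusters by a
deterministic greedy centroid pass: sequences are visited in order of
decreasing length (ties broken by ID), each joining the first existing
centroid whose global-alignment identity reaches the threshold, or founding
a new cluster.  An external clusterer's membership table can be imported in
the same TSV layout instead.  A pairwise-identity coherence check serves as
cluster quality control, and the rank-size distribution of cluster sizes can
be fitted with exponential-decay and Hill models.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import curve_fit

from .align import global_identity, quick_identity_bound

logger = logging.getLogger(__name__)


@dataclass
class Cluster:
    cluster_id: int
    member_ids: list[str]
    representative_id: str

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass
class ClusterSet:
    clusters: list[Cluster] = field(default_factory=list)
    identity_threshold: float | None = None

    def __len__(self) -> int:
        return len(self.clusters)

    def sizes(self) -> list[int]:
        return sorted((len(c) for c in self.clusters), reverse=True)

    def member_to_cluster(self) -> dict[str, int]:
        return {
            pid: c.cluster_id for c in self.clusters for pid in c.member_ids
        }


def greedy_cluster(
    sequences: Mapping[str, str], identity_threshold: float = 0.8
) -> ClusterSet:
    """Greedy centroid clustering at a fixed global-identity threshold.

    Deterministic for a fixed input set: the visit order is length
    descending, ties by ID lexicographic, which also makes the result
    independent of input (file) order.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0, 1]")
    if not sequences:
        raise ValueError("no sequences to cluster")
    order = sorted(sequences, key=lambda pid: (-len(sequences[pid]), pid))
    clusters: list[Cluster] = []
    centroid_seqs: list[str] = []
    for pid in order:
        seq = sequences[pid]
        placed = False
        for cluster, cseq in zip(clusters, centroid_seqs):
            if quick_identity_bound(seq, cseq) < identity_threshold:
                continue
            if global_identity(seq, cseq) >= identity_threshold:
                cluster.member_ids.append(pid)
                placed = True
                break
        if not placed:
            clusters.append(
                Cluster(
                    cluster_id=len(clusters),
                    member_ids=[pid],
                    representative_id=pid,
                )
            )
            centroid_seqs.append(seq)
    return ClusterSet(clusters=clusters, identity_threshold=identity_threshold)


def drop_singletons(cs: ClusterSet) -> ClusterSet:
    """Exclude single-sequence clusters before conservation scoring.

    A singleton means the protein is either unconserved or identical across
    genomes — the latter is already handled by the identical-protein spread
    report — so only multi-member clusters proceed.
    """
    kept = [c for c in cs.clusters if len(c) >= 2]
    n_dropped = len(cs.clusters) - len(kept)
    if n_dropped:
        logger.info("dropped %d singleton clusters", n_dropped)
    if not kept:
        logger.warning("all clusters were singletons")
    return ClusterSet(clusters=kept, identity_threshold=cs.identity_threshold)


def coherence_check(
    cluster: Cluster,
    sequences: Mapping[str, str],
    min_identity: float = 0.5,
    max_pairs: int = 200,
    seed: int = 0,
) -> tuple[bool, float]:
    """Pairwise-identity quality control for one cluster.

    Computes all pairwise global identities (or a seeded sample of at most
    ``max_pairs`` pairs for clusters with more than 20 members) and passes
    iff the minimum observed identity reaches ``min_identity``.
    """
    ids = sorted(cluster.member_ids)
    if len(ids) < 2:
        raise ValueError("coherence check requires >= 2 members")
    pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]
    if len(ids) > 20 and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[int(i)] for i in sorted(idx)]
    min_seen = 1.0
    for a, b in pairs:
        ident = global_identity(sequences[a], sequences[b])
        min_seen = min(min_seen, ident)
    return min_seen >= min_identity, min_seen


def _exponential(x: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * np.exp(-b * x)


def _hill(x: np.ndarray, a: float, c: float, h: float) -> np.ndarray:
    return a * x**h / (c**h + x**h)


def fit_rank_size(sizes: Iterable[int]) -> dict[str, dict]:
    """Fit the rank-size curve of cluster sizes.

    Duplicated sizes are collapsed to a single point before fitting, ranks
    are 1-based along the descending curve.  Two least-squares models are
    fitted: exponential decay ``a * exp(-b * x)`` and a Hill curve
    ``a * x^h / (c^h + x^h)`` (h may be negative, giving a decreasing
    sigmoid).  Each entry reports parameters and R^2 = 1 - SS_res/SS_tot;
    non-convergence or a degenerate flat curve yields R^2 = NaN with the
    ``converged`` flag cleared, never an exception.
    """
    unique_sizes = sorted(set(int(s) for s in sizes), reverse=True)
    if len(unique_sizes) == 1:
        # constant curve: SS_tot = 0, R^2 undefined — flagged, not an error
        return {
            name: {"params": None, "r_squared": float("nan"), "converged": False}
            for name in ("exponential", "hill")
        }
    if len(unique_sizes) < 4:
        raise ValueError("need >= 4 distinct cluster sizes to fit")
    y = np.asarray(unique_sizes, dtype=float)
    x = np.arange(1, len(y) + 1, dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    results: dict[str, dict] = {}

    def try_fit(name, fn, p0, bounds):
        if ss_tot == 0.0:
            results[name] = {"params": None, "r_squared": float("nan"),
                             "converged": False}
            return
        try:
            popt, _ = curve_fit(fn, x, y, p0=p0, bounds=bounds, maxfev=20000)
            resid = y - fn(x, *popt)
            r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
            if not math.isfinite(r2):
                raise RuntimeError("non-finite fit")
            results[name] = {"params": [float(p) for p in popt],
                             "r_squared": r2, "converged": True}
        except Exception:
            results[name] = {"params": None, "r_squared": float("nan"),
                             "converged": False}

    try_fit("exponential", _exponential,
            p0=[y[0], 0.5], bounds=([0, 0], [np.inf, np.inf]))
    try_fit("hill", _hill,
            p0=[y[0], max(len(y) / 2.0, 1.0), -1.0],
            bounds=([0, 1e-9, -50], [np.inf, np.inf, 50]))
    return results


def write_clusters_tsv(cs: ClusterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tprotein_id\n")
        for c in cs.clusters:
            for pid in sorted(c.member_ids):
                fh.write(f"{c.cluster_id}\t{pid}\n")


def read_clusters_tsv(path: str | Path) -> ClusterSet:
    """Import cluster membership from TSV (own output or external clusterer)."""
    members: dict[int, list[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("cluster_id"):
            raise ValueError("cluster TSV must start with a cluster_id header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cid_s, pid = line.split("\t")
            members.setdefault(int(cid_s), []).append(pid)
    clusters = [
        Cluster(cluster_id=cid, member_ids=pids,
                representative_id=min(pids))
        for cid, pids in sorted(members.items())
    ]
    return ClusterSet(clusters=clusters)
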