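"""Category enrichment statistics for syntenic and cluster gene lists.

Given an observation list (e.g. the conserved syntenic KOs of the selected
clusters, or the COG classes of cluster proteins) and a population list (the
annotated proteins of a reference genome), each category is scored with

* fold enrichment        FE = (k/n) / (K/N),
* a hypergeometric upper-tail p-value  P(X >= k) for k successes among n
  draws without replacement from a population of N with K successes,
* an odds ratio on the 2x2 table a=k, b=n-k, c=K-k, d=(N-K)-b, with a
  Haldane-Anscombe +0.5 correction (flagged) when any cell is zero,
* Benjamini-Hochberg step-up q-values  q(i) = min_{j>=i} p(j) * m / j,

where k counts observation-list members of the category, n the observation
list size, K the category's population members and N the population size.
The hypergeometric tail is summed in log space for numerical stability.
Aggregate mode tests all categories in one family; per-cluster mode adjusts
each cluster's tests independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp


@dataclass(frozen=True)
class CategoryCounts:
    category_id: str
    k: int
    n: int
    K: int
    N: int

    def validate(self) -> None:
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"invalid counts for {self.category_id}: "
                             f"need K <= N and n <= N")
        if not (max(0, self.n + self.K - self.N) <= self.k <= min(self.K, self.n)):
            raise ValueError(
                f"invalid k for {self.category_id}: "
                f"k={self.k} outside [max(0, n+K-N), min(K, n)]"
            )


@dataclass
class EnrichmentResult:
    category_id: str
    cluster_id: int | str | None
    k: int
    n: int
    K: int
    N: int
    fold_enrichment: float
    p_value: float
    odds_ratio: float
    or_corrected: bool
    q_value: float = float("nan")
    excluded: bool = False  # category absent from the population


def fold_enrichment(c: CategoryCounts) -> float:
    """FE = (k/n) / (K/N); the observation rate relative to the population."""
    if c.n == 0 or c.K == 0 or c.N == 0:
        raise ValueError(
            f"fold enrichment undefined for {c.category_id}: n, K, N must be > 0"
        )
    return (c.k / c.n) / (c.K / c.N)


def _log_hypergeom_pmf(i: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    return (
        gammaln(K + 1) - gammaln(i + 1) - gammaln(K - i + 1)
        + gammaln(N - K + 1) - gammaln(n - i + 1) - gammaln(N - K - n + i + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def hypergeom_pvalue(c: CategoryCounts) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Sums C(K,i) C(N-K,n-i) / C(N,n) for i from k to min(K, n), in log space.
    """
    c.validate()
    upper = min(c.K, c.n)
    if c.k <= max(0, c.n + c.K - c.N):
        return 1.0
    i = np.arange(c.k, upper + 1, dtype=float)
    log_terms = _log_hypergeom_pmf(i, c.N, c.K, c.n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def odds_ratio(c: CategoryCounts) -> tuple[float, bool]:
    """OR = (a*d)/(b*c) with a=k, b=n-k, c=K-k, d=(N-K)-b.

    Any zero cell triggers the Haldane-Anscombe correction: +0.5 is added to
    all four cells and the ``corrected`` flag is set.
    """
    c.validate()
    a = c.k
    b = c.n - c.k
    cc = c.K - c.k
    d = (c.N - c.K) - b
    if d < 0:
        raise ValueError(f"inconsistent 2x2 table for {c.category_id}")
    if 0 in (a, b, cc, d):
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (cc + 0.5)), True
    return (a * d) / (b * cc), False


def bh_fdr(pvalues: Sequence[float], m: int | None = None) -> list[float]:
    """Benjamini-Hochberg step-up q-values, q(i) = min_{j>=i} p(j) * m / j.

    ``m`` is the total number of tests (defaults to the number of p-values;
    it may be larger when only a subset of a test family is supplied).
    Values are capped at 1 and returned in the input order; tied p-values
    receive equal q-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m_total = len(p) if m is None else int(m)
    if m_total < len(p):
        raise ValueError("m must be >= number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m_total / np.arange(1, len(p) + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return [float(v) for v in q]


def _count_categories(
    items: Iterable[str], category_map: Mapping[str, Sequence[str]]
) -> tuple[dict[str, int], int]:
    """Category tallies for a list of items (each item counts once per
    category it belongs to); returns (per-category counts, list size)."""
    counts: dict[str, int] = {}
    n = 0
    for item in items:
        n += 1
        for cat in set(category_map.get(item, ())):
            counts[cat] = counts.get(cat, 0) + 1
    return counts, n


def enrich(
    observation: Sequence[str] | Mapping[int | str, Sequence[str]],
    population: Sequence[str],
    category_map: Mapping[str, Sequence[str]],
    mode: str = "aggregate",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Enrichment table for an observation list against a population.

    In ``aggregate`` mode the observation is one list and all categories
    form a single BH family.  In ``per_cluster`` mode the observation is a
    mapping cluster_id -> list, and the BH correction is applied
    independently within each cluster (m = categories tested for that
    cluster).  Categories observed but absent from the population are
    reported with the ``excluded`` flag (FE and p undefined) and do not
    enter the test family.
    """
    if mode not in ("aggregate", "per_cluster"):
        raise ValueError(f"unknown mode {mode!r}")
    if not population:
        raise ValueError("population list is empty")
    pop_counts, N = _count_categories(population, category_map)

    groups: dict[int | str | None, Sequence[str]]
    if mode == "aggregate":
        if isinstance(observation, Mapping):
            raise TypeError("aggregate mode takes a flat observation list")
        groups = {None: observation}
    else:
        if not isinstance(observation, Mapping):
            raise TypeError("per_cluster mode takes a cluster_id -> list mapping")
        groups = dict(observation)

    results: list[EnrichmentResult] = []
    for cluster_id in groups:
        obs_counts, n = _count_categories(groups[cluster_id], category_map)
        testable: list[EnrichmentResult] = []
        for cat in sorted(obs_counts):
            k = obs_counts[cat]
            K = pop_counts.get(cat, 0)
            if K == 0:
                # mirrors manual exclusion of categories missing from the
                # reference genome: reported, never tested
                results.append(EnrichmentResult(
                    category_id=cat, cluster_id=cluster_id, k=k, n=n, K=0,
                    N=N, fold_enrichment=float("nan"), p_value=float("nan"),
                    odds_ratio=float("nan"), or_corrected=False,
                    excluded=True,
                ))
                continue
            counts = CategoryCounts(category_id=cat, k=min(k, K, n), n=n, K=K, N=N)
            if counts.k != k:
                raise ValueError(
                    f"category {cat}: observed count {k} exceeds population "
                    "capacity; observation must draw from the population"
                )
            fe = fold_enrichment(counts)
            p = hypergeom_pvalue(counts)
            orv, corrected = odds_ratio(counts)
            res = EnrichmentResult(
                category_id=cat, cluster_id=cluster_id, k=k, n=n, K=K, N=N,
                fold_enrichment=fe, p_value=p, odds_ratio=orv,
                or_corrected=corrected,
            )
            testable.append(res)
            results.append(res)
        if testable:
            qs = bh_fdr([r.p_value for r in testable])
            for r, q in zip(testable, qs):
                r.q_value = q

    df = pd.DataFrame(
        {
            "cluster_id": [r.cluster_id for r in results],
            "category": [r.category_id for r in results],
            "k": [r.k for r in results],
            "n": [r.n for r in results],
            "K": [r.K for r in results],
            "N": [r.N for r in results],
            "FE": [r.fold_enrichment for r in results],
            "p": [r.p_value for r in results],
            "OR": [r.odds_ratio for r in results],
            "corrected": [r.or_corrected for r in results],
            "q": [r.q_value for r in results],
            "excluded": [r.excluded for r in results],
        }
    )
    df["significant_p"] = (df["p"] < alpha) & ~df["excluded"]
    df["significant_q"] = (df["q"] < alpha) & ~df["excluded"]
    if mode == "aggregate":
        df = df.drop(columns=["cluster_id"])
    return df


def read_category_map(path: str, key_col: int = 0, cat_col: int = 1) -> dict[str, list[str]]:
    """Load a TSV mapping items to categories (multi-row = multi-membership)."""
    mapping: dict[str, list[str]] = {}
    with open(path) as fh:
        header = fh.readline()  # header row required
        if "\t" not in header:
            raise ValueError("category map must be a TSV with a header")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) <= max(key_col, cat_col) or not parts[key_col]:
                continue
            mapping.setdefault(parts[key_col], []).append(parts[cat_col])
    return mapping
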