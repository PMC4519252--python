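"""Over-representation analysis against flat term collections.

For a query gene set of size n drawn from a background of N annotated
genes, the overlap k with a term of size K is scored by the
hypergeometric upper tail P(X >= k) — the probability of an overlap at
least as large under sampling without replacement. P-values are
corrected across all terms of a collection with the Benjamini-Hochberg
step-up procedure and flagged significant below an adjusted-p
threshold (default 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TermCollection",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "hypergeom_upper_tail",
    "bh_adjust",
    "enrich_terms",
]


@dataclass
class TermCollection:
    """Flat term -> gene-set annotations over a fixed background."""

    terms: dict[str, tuple[str, frozenset[str]]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        if not self.background:
            raise ValueError("background must be non-empty")
        for term_id, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {term_id} annotates no genes")
            if not genes <= self.background:
                raise ValueError(f"term {term_id} annotates genes outside the background")


def read_gmt(path: str | Path, background: Iterable[str] | None = None) -> TermCollection:
    """Read a GMT file (term_id <TAB> description <TAB> gene...).

    The background defaults to the union of all annotated genes.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{line_no}: GMT line needs id, description, >=1 gene")
        terms[parts[0]] = (parts[1], frozenset(g for g in parts[2:] if g))
    bg = frozenset(background) if background is not None else frozenset().union(
        *(genes for _, genes in terms.values())
    )
    return TermCollection(terms=terms, background=bg)


def write_gmt(collection: TermCollection, path: str | Path) -> None:
    lines = []
    for term_id in sorted(collection.terms):
        name, genes = collection.terms[term_id]
        lines.append("\t".join([term_id, name, *sorted(genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    Survival-function evaluation in log space; exactly 1.0 for k <= 0.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent hypergeometric counts k={k} K={K} n={n} N={N}")
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, preserving input order.

    Sorted p_(i) is multiplied by m/i, monotonicity is enforced by a
    running minimum from the largest p down, values are capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted.tolist()


@dataclass
class EnrichmentResult:
    term_id: str
    name: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_adj: float
    significant: bool


def enrich_terms(
    query: Iterable[str], collection: TermCollection, alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Score every term of a collection against a query gene set.

    Query genes outside the background are dropped (with a logged
    count); BH correction spans all terms of the collection; output is
    sorted by adjusted p, then term id.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    query_set = set(query)
    in_bg = query_set & collection.background
    dropped = len(query_set) - len(in_bg)
    if dropped:
        logger.info("dropped %d query genes outside the background", dropped)
    if not in_bg:
        logger.warning("query empty after background intersection")
        return []

    N = len(collection.background)
    n = len(in_bg)
    term_ids = sorted(collection.terms)
    raw = []
    for term_id in term_ids:
        _, genes = collection.terms[term_id]
        k = len(in_bg & genes)
        raw.append(hypergeom_upper_tail(k, len(genes), n, N))
    adjusted = bh_adjust(raw)

    results = [
        EnrichmentResult(
            term_id=term_id,
            name=collection.terms[term_id][0],
            k=len(in_bg & collection.terms[term_id][1]),
            K=len(collection.terms[term_id][1]),
            n=n,
            N=N,
            p_raw=p,
            p_adj=q,
            significant=q < alpha,
        )
        for term_id, p, q in zip(term_ids, raw, adjusted)
    ]
    results.sort(key=lambda r: (r.p_adj, r.term_id))
    return results
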