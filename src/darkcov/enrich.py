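"""Over-representation testing of gene sets against a background.

The statistic is the one-sided (upper-tail) hypergeometric probability —
equivalently Fisher's exact test's enrichment tail: given a universe of N
genes of which K carry a term, and a study set of n genes of which k carry
it, p = P(X >= k) for X ~ Hypergeometric(N, K, n). Multiple testing is
controlled with Benjamini–Hochberg q-values across the surviving terms.

Two standard contrasts are wired on top: dark-body mapped genes against the
whole annotation ("dark vs genome"), and dark-CDS mapped genes against the
remaining mapped genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .models import DarkCoverageReport, TermMap

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "ContrastOutcome",
    "hypergeom_upper_tail",
    "bh_fdr",
    "enrich",
    "run_contrasts",
]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int  # study genes carrying the term
    n: int  # study genes present in the universe
    K: int  # universe genes carrying the term
    N: int  # universe size
    p_value: float
    q_value: float
    study_genes: FrozenSet[str] = frozenset()


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    Arguments follow the over-representation convention: k hits among a
    study of size n, with K annotated genes in a universe of size N.
    """
    for label, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if not isinstance(v, (int, np.integer)) or v < 0:
            raise ValueError(f"{label} must be a non-negative integer, got {v!r}")
    if k > n or k > K or n > N or K > N:
        raise ValueError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N} "
            "(need k <= min(n, K) and n, K <= N)"
        )
    if k == 0:
        return 1.0  # P(X >= 0); also covers the degenerate empty universe
    # survival function at k-1 gives P(X >= k); scipy evaluates in log space
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def enrich(
    study: Iterable[str],
    universe: Iterable[str],
    terms: TermMap,
    min_term_size: int = 3,
) -> List[EnrichmentResult]:
    """Test every term for over-representation of ``study`` within ``universe``.

    Study genes outside the universe are dropped (logged). Terms are
    restricted to their universe members and kept when >= ``min_term_size``
    of them remain; no upper size filter is applied. Results are sorted by
    (p, term_id).
    """
    universe_set = set(universe)
    study_in = set(study) & universe_set
    dropped = len(set(study)) - len(study_in)
    if dropped:
        logger.warning("%d study genes outside the universe were dropped", dropped)
    if not study_in:
        raise ValueError("study set is empty after intersection with the universe")

    N, n = len(universe_set), len(study_in)
    surviving: List[tuple] = []
    for term_id in sorted(terms.terms):
        members = terms.terms[term_id] & universe_set
        K = len(members)
        if K < min_term_size:
            continue
        hits = members & study_in
        surviving.append((term_id, len(hits), K, frozenset(hits)))
    if not surviving:
        return []

    p_values = [hypergeom_upper_tail(k, K, n, N) for _, k, K, _ in surviving]
    q_values = bh_fdr(p_values)
    results = [
        EnrichmentResult(
            term_id=term_id,
            k=k,
            n=n,
            K=K,
            N=N,
            p_value=p,
            q_value=float(q),
            study_genes=hits,
        )
        for (term_id, k, K, hits), p, q in zip(surviving, p_values, q_values)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


@dataclass
class ContrastOutcome:
    """Result of one enrichment contrast, or an explicit empty outcome."""

    name: str
    study_size: int
    universe_size: int
    results: List[EnrichmentResult]
    message: Optional[str] = None


def run_contrasts(
    reports: Dict[str, DarkCoverageReport],
    grl_gene_ids: Iterable[str],
    all_gene_ids: Iterable[str],
    terms: TermMap,
    min_term_size: int = 3,
) -> Dict[str, ContrastOutcome]:
    """The two standard contrasts over per-gene dark reports.

    ``dark_vs_genome``: mapped genes with any dark body, against all
    annotated genes. ``dark_cds_vs_grl``: mapped genes with any dark CDS,
    against all mapped genes. An empty study yields an explicit
    no-study-genes outcome rather than an error.
    """
    grl_ids = list(dict.fromkeys(grl_gene_ids))
    all_ids = list(dict.fromkeys(all_gene_ids))
    dark_body = [
        g for g in grl_ids if g in reports and reports[g].any_dark_body
    ]
    dark_cds = [g for g in grl_ids if g in reports and reports[g].any_dark_cds]

    outcomes: Dict[str, ContrastOutcome] = {}
    for name, study, universe in (
        ("dark_vs_genome", dark_body, all_ids),
        ("dark_cds_vs_grl", dark_cds, grl_ids),
    ):
        if not study:
            outcomes[name] = ContrastOutcome(
                name, 0, len(universe), [], message="no study genes"
            )
            continue
        outcomes[name] = ContrastOutcome(
            name,
            len(set(study) & set(universe)),
            len(set(universe)),
            enrich(study, universe, terms, min_term_size=min_term_size),
        )
    return outcomes
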