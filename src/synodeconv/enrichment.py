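"""Hypergeometric GO over-representation analysis with Bonferroni control.

The upper-tail hypergeometric p value is computed from first principles
as an exact log-space sum of hypergeometric point masses, which keeps it
numerically stable for genome-scale universes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io import GOAnnotation

__all__ = ["EnrichmentResult", "hypergeometric_overrep", "enrich"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    """One tested term: overlap counts, raw p, Bonferroni-adjusted p."""

    term_id: str
    term_name: str
    overlap_count: int
    term_size: int
    list_size: int
    universe_size: int
    p_value: float
    p_adjusted: float
    gene_group: str = ""


def _log_hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    """log P(X = k) for X ~ Hypergeometric(N, K, n)."""
    return (
        math.lgamma(K + 1)
        - math.lgamma(k + 1)
        - math.lgamma(K - k + 1)
        + math.lgamma(N - K + 1)
        - math.lgamma(n - k + 1)
        - math.lgamma(N - K - n + k + 1)
        - (math.lgamma(N + 1) - math.lgamma(n + 1) - math.lgamma(N - n + 1))
    )


def hypergeometric_overrep(
    overlap: int, list_size: int, term_size: int, universe_size: int
) -> float:
    """Upper-tail p = P(X >= overlap), X ~ Hypergeometric(universe, term, list).

    Exact tail sum accumulated in log space (log-sum-exp over point
    masses), so large counts do not underflow.
    """
    if not (0 <= overlap <= min(list_size, term_size)):
        raise ValueError(
            f"overlap {overlap} inconsistent with list {list_size}, term {term_size}"
        )
    if term_size > universe_size or list_size > universe_size:
        raise ValueError("term and list sizes must not exceed the universe size")
    if overlap == 0:
        return 1.0
    k_min = max(0, list_size + term_size - universe_size)
    k_max = min(list_size, term_size)
    logs = [
        _log_hypergeom_pmf(k, universe_size, term_size, list_size)
        for k in range(max(overlap, k_min), k_max + 1)
    ]
    if not logs:
        return 1.0
    m = max(logs)
    p = math.exp(m) * sum(math.exp(x - m) for x in logs)
    return min(1.0, p)


def enrich(
    gene_list: Iterable[str],
    annotation: GOAnnotation,
    universe: Iterable[str],
    group_label: str = "",
) -> list[EnrichmentResult]:
    """Test every annotation term against a selected gene list.

    Terms are intersected with the universe first and only terms with a
    non-empty intersection are tested; Bonferroni m = number of terms
    tested in this run. Results are sorted by p value, ties by term id.
    """
    universe_set = frozenset(universe)
    if not universe_set:
        raise ValueError("empty universe")
    gene_set = frozenset(gene_list)
    extra = gene_set - universe_set
    if extra:
        raise ValueError(f"gene list not contained in universe: {sorted(extra)[:5]}")
    if not gene_set:
        logger.warning("empty gene list for group %r: returning no results", group_label)
        return []

    tested: list[tuple[str, str, int, int, float]] = []
    for term_id, (term_name, term_genes) in sorted(annotation.terms.items()):
        in_universe = term_genes & universe_set
        if not in_universe:
            continue
        overlap = len(in_universe & gene_set)
        p = hypergeometric_overrep(
            overlap, len(gene_set), len(in_universe), len(universe_set)
        )
        tested.append((term_id, term_name, overlap, len(in_universe), p))

    m = len(tested)
    results = [
        EnrichmentResult(
            term_id=tid,
            term_name=tname,
            overlap_count=k,
            term_size=size,
            list_size=len(gene_set),
            universe_size=len(universe_set),
            p_value=p,
            p_adjusted=min(1.0, p * m),
            gene_group=group_label,
        )
        for tid, tname, k, size, p in tested
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate results in report shape: ID, Description, Count, P value, Gene group."""
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "term_name": [r.term_name for r in results],
            "overlap_count": [r.overlap_count for r in results],
            "term_size": [r.term_size for r in results],
            "p_value": [r.p_value for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "gene_group": [r.gene_group for r in results],
        }
    )
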