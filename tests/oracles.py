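"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's code paths: plain Python loops,
exact rational arithmetic, and closed-form formulas only.
"""

from __future__ import annotations

import math
from fractions import Fraction


def running_sum_es_oracle(ranked, signature_genes) -> float:
    """Step-by-step running sum: +1/|S| on hits, -1/(N-|S|) on misses.

    Returns the signed value of maximal absolute deviation (first maximal
    index wins ties), accumulated in exact rational arithmetic and
    rounded to float only at the end.
    """
    sig = set(signature_genes)
    n = len(ranked)
    n_hits = sum(1 for g in ranked if g in sig)
    assert 0 < n_hits < n
    up = Fraction(1, n_hits)
    down = Fraction(1, n - n_hits)
    total = Fraction(0)
    best = Fraction(0)
    best_abs = Fraction(-1)
    for g in ranked:
        total = total + up if g in sig else total - down
        if abs(total) > best_abs:
            best_abs = abs(total)
            best = total
    return float(best)


def hypergeom_tail_oracle(overlap: int, list_size: int, term_size: int, universe: int) -> float:
    """P(X >= overlap) by direct summation of exact binomial-coefficient ratios."""
    denom = math.comb(universe, list_size)
    total = Fraction(0)
    for k in range(overlap, min(list_size, term_size) + 1):
        if list_size - k > universe - term_size:
            continue
        total += Fraction(
            math.comb(term_size, k) * math.comb(universe - term_size, list_size - k), denom
        )
    return float(min(total, Fraction(1)))


def welch_ttest_oracle(a, b) -> tuple[float, float]:
    """Two-sided Welch t-test from the textbook formulas (Satterthwaite df)."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, float(p)


def pearson_oracle(x, y) -> float:
    """Product-moment correlation from the direct formula."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def quantile_normalize_oracle(columns: list[list[float]]) -> list[list[float]]:
    """Naive quantile normalization (no ties expected in the input)."""
    n = len(columns[0])
    sorted_cols = [sorted(c) for c in columns]
    reference = [sum(col[i] for col in sorted_cols) / len(columns) for i in range(n)]
    out = []
    for c in columns:
        ranks = sorted(range(n), key=lambda i: c[i])
        new = [0.0] * n
        for pos, i in enumerate(ranks):
            new[i] = reference[pos]
        out.append(new)
    return out
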