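"""Per-gene two-group statistics, signed fold changes, Bonferroni, and gene selection.

Supports cross-sectional contrasts (group A vs group B at a timepoint,
Welch t-test by default) and longitudinal contrasts (paired t-test on
within-patient differences). Degenerate zero-variance cases follow
documented conventions so simulation loops never raise: both groups
constant and equal -> t=0, p=1; constant and unequal -> p=0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

__all__ = [
    "DEResult",
    "ttest_per_gene",
    "signed_fold_change",
    "bonferroni",
    "select_de_genes",
    "differential_expression",
]

P_NOMINAL_DEFAULT = 0.05
FC_THRESHOLD_DEFAULT = 1.2


@dataclass(frozen=True)
class DEResult:
    """Per-gene differential-expression statistics for one contrast.

    ``fold_change`` uses the signed convention: r = 2^(meanA - meanB);
    FC = r if r >= 1 else -1/r, so |FC| >= 1 always and negative entries
    mark genes higher in group B. ``direction`` is 'up_in_A', 'up_in_B',
    or 'none' (exactly equal means).
    """

    genes: tuple[str, ...]
    t_statistic: np.ndarray
    p_value: np.ndarray
    p_bonferroni: np.ndarray
    fold_change: np.ndarray
    direction: tuple[str, ...]
    contrast: str = ""

    def __post_init__(self) -> None:
        n = len(self.genes)
        for name in ("t_statistic", "p_value", "p_bonferroni", "fold_change"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per gene")
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "gene_id": list(self.genes),
                "t_statistic": self.t_statistic,
                "p_value": self.p_value,
                "p_bonferroni": self.p_bonferroni,
                "fold_change": self.fold_change,
                "direction": list(self.direction),
            }
        )
        return df.sort_values(["p_value", "gene_id"], kind="stable").reset_index(drop=True)


def ttest_per_gene(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    paired: bool = False,
    equal_var: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided per-gene t statistics and p values for group A vs group B.

    Unpaired contrasts use the Welch t-test by default (``equal_var=True``
    switches to the pooled-variance Student test). Paired contrasts test
    the within-pair differences a_i - b_i; callers must pass the two
    groups in matched order.

    Returns ``(t, p)`` arrays aligned with ``matrix.genes``.
    """
    group_a = list(group_a)
    group_b = list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError(
            f"each group needs >=2 samples (got {len(group_a)} and {len(group_b)})"
        )
    A = matrix.values[:, [matrix.sample_index(s) for s in group_a]]
    B = matrix.values[:, [matrix.sample_index(s) for s in group_b]]
    # degenerate genes are post-corrected below; silence the warnings
    # scipy emits while computing their (discarded) statistics
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if paired:
            if len(group_a) != len(group_b):
                raise ValueError("paired contrast needs equal-size matched groups")
            res = stats.ttest_rel(A, B, axis=1)
            zero_var = np.std(A - B, axis=1) == 0
            equal_means = np.mean(A - B, axis=1) == 0
        else:
            res = stats.ttest_ind(A, B, axis=1, equal_var=equal_var)
            zero_var = (np.std(A, axis=1) == 0) & (np.std(B, axis=1) == 0)
            equal_means = np.mean(A, axis=1) == np.mean(B, axis=1)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # degenerate conventions: zero variance with equal means -> (0, 1);
    # zero variance with unequal means -> infinitely strong evidence (p=0)
    t = np.where(zero_var & equal_means, 0.0, t)
    p = np.where(zero_var & equal_means, 1.0, p)
    sign = np.sign(np.mean(A, axis=1) - np.mean(B, axis=1))
    with np.errstate(invalid="ignore"):
        t = np.where(zero_var & ~equal_means, sign * np.inf, t)
    p = np.where(zero_var & ~equal_means, 0.0, p)
    bad = ~np.isfinite(p)
    if np.any(bad):
        raise ValueError(f"undefined p value for gene {matrix.genes[int(np.argmax(bad))]!r}")
    return t, p


def signed_fold_change(
    matrix: ExpressionMatrix, group_a: Sequence[str], group_b: Sequence[str]
) -> np.ndarray:
    """Signed fold change on the linear scale from log2 group means.

    r = 2^(mean_log2_A - mean_log2_B); returns r when r >= 1 and -1/r
    otherwise, so magnitudes are symmetric around +/-1.
    """
    group_a = list(group_a)
    group_b = list(group_b)
    if not group_a or not group_b:
        raise ValueError("groups must be non-empty")
    A = matrix.values[:, [matrix.sample_index(s) for s in group_a]]
    B = matrix.values[:, [matrix.sample_index(s) for s in group_b]]
    diff = A.mean(axis=1) - B.mean(axis=1)
    r = np.exp2(diff)
    return np.where(r >= 1.0, r, -1.0 / r)


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """p' = min(1, p * m); m defaults to the number of p values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m={m} smaller than the number of tests ({p.size})")
    return np.minimum(1.0, p * m)


def differential_expression(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    paired: bool = False,
    equal_var: bool = False,
    contrast: str = "",
) -> DEResult:
    """Full per-gene contrast: t-test, signed FC, direction, Bonferroni over all genes tested."""
    t, p = ttest_per_gene(matrix, group_a, group_b, paired=paired, equal_var=equal_var)
    fc = signed_fold_change(matrix, group_a, group_b)
    direction = tuple(
        "up_in_A" if f > 1.0 else ("up_in_B" if f < -1.0 else "none") for f in fc
    )
    return DEResult(
        genes=matrix.genes,
        t_statistic=t,
        p_value=p,
        p_bonferroni=bonferroni(p),
        fold_change=fc,
        direction=direction,
        contrast=contrast,
    )


def select_de_genes(
    result: DEResult,
    p_nominal: float = P_NOMINAL_DEFAULT,
    fc_threshold: float = FC_THRESHOLD_DEFAULT,
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Genes with nominal p < p_nominal and |FC| > fc_threshold, split by direction.

    Both inequalities are strict; a gene exactly at a threshold is excluded.
    Returns ``(genes_up_in_A, genes_up_in_B)``.
    """
    keep = (result.p_value < p_nominal) & (np.abs(result.fold_change) > fc_threshold)
    up_a = tuple(
        g for g, k, d in zip(result.genes, keep, result.direction) if k and d == "up_in_A"
    )
    up_b = tuple(
        g for g, k, d in zip(result.genes, keep, result.direction) if k and d == "up_in_B"
    )
    return up_a, up_b
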