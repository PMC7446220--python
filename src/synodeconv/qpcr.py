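"""Relative qPCR quantification (2^-ddCt) and correlation with array expression."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import QpcrTable

__all__ = ["DdctResult", "ddct_fold_change", "pearson_correlation"]


@dataclass(frozen=True)
class DdctResult:
    """Per-sample relative quantification of one target gene.

    delta_ct = Ct_target - Ct_endogenous; delta_delta_ct is taken versus
    the calibrator's delta_ct; fold_change = 2^(-delta_delta_ct), so
    fold_change is 1 exactly when ddCt is 0.
    """

    target_gene: str
    samples: tuple[str, ...]
    delta_ct: np.ndarray
    delta_delta_ct: np.ndarray
    fold_change: np.ndarray
    calibrator: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.samples),
                "gene_id": self.target_gene,
                "delta_ct": self.delta_ct,
                "delta_delta_ct": self.delta_delta_ct,
                "fold_change": self.fold_change,
            }
        )


def ddct_fold_change(
    table: QpcrTable,
    target_gene: str,
    calibrator: str | Sequence[str],
) -> DdctResult:
    """Fold change 2^(-ddCt) of a target gene across all samples in the table.

    ``calibrator`` is either a single sample id or a group of sample ids
    whose mean delta-Ct serves as the reference. Technical replicates are
    averaged on the Ct scale before any differencing.
    """
    samples = table.sample_ids
    delta = {}
    for s in samples:
        ct_t = table.ct(s, target_gene)
        ct_e = table.ct(s, table.endogenous_gene)
        delta[s] = ct_t - ct_e
    if isinstance(calibrator, str):
        cal_samples = [calibrator]
    else:
        cal_samples = list(calibrator)
    unknown = [s for s in cal_samples if s not in delta]
    if unknown:
        raise KeyError(f"calibrator sample(s) not in table: {unknown}")
    cal_delta = float(np.mean([delta[s] for s in cal_samples]))
    d = np.array([delta[s] for s in samples])
    dd = d - cal_delta
    return DdctResult(
        target_gene=target_gene,
        samples=samples,
        delta_ct=d,
        delta_delta_ct=dd,
        fold_change=np.exp2(-dd),
        calibrator=",".join(cal_samples),
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Product-moment correlation with two-sided p from the t transform.

    Returns ``(r, r_squared, p_value)``; p uses t = r * sqrt((n-2) /
    (1-r^2)) on n-2 degrees of freedom. Both vectors must have equal
    length >= 3 and be non-constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("correlation needs at least 3 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sx2 = float((dx**2).sum())
    sy2 = float((dy**2).sum())
    if sx2 == 0 or sy2 == 0:
        raise ValueError("correlation undefined for constant input")
    # single sqrt of the product: y = +/-x then yields exactly +/-1
    r = float((dx * dy).sum() / np.sqrt(sx2 * sy2))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return r, r * r, p
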