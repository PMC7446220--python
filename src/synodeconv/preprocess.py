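"""Raw intensities -> analysis-ready matrix: log2, quantile normalization, batch adjustment.

Gene and sample order never change through any of these transforms, and
the matrix scale tag only moves forward (raw -> log2 -> log2_quantile ->
log2_quantile_batchadj).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .io import ExpressionMatrix, Scale

__all__ = ["log2_transform", "quantile_normalize", "batch_adjust"]

DEFAULT_LOG2_OFFSET = 1.0


def log2_transform(matrix: ExpressionMatrix, offset: float = DEFAULT_LOG2_OFFSET) -> ExpressionMatrix:
    """log2(value + offset) on a raw-scale matrix.

    ``offset`` guards zeros (default 1.0); every value + offset must be
    strictly positive.
    """
    if matrix.scale != Scale.raw:
        raise ValueError(f"log2_transform expects a raw-scale matrix, got {matrix.scale.name}")
    if offset < 0:
        raise ValueError(f"offset must be non-negative, got {offset}")
    shifted = matrix.values + offset
    if np.any(shifted <= 0):
        i, j = np.argwhere(shifted <= 0)[0]
        raise ValueError(
            f"non-positive value {matrix.values[i, j]} + offset {offset} for gene "
            f"{matrix.genes[i]!r}, sample {matrix.samples[j]!r}"
        )
    return matrix.with_values(np.log2(shifted), Scale.log2)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean-of-order-statistics distribution.

    After normalization all columns share the same sorted values (the
    across-sample mean of the order statistics) and within-column ranks
    are preserved. Ties within a column receive the mean of the reference
    quantiles they span, which makes the transform order-independent and
    idempotent.
    """
    if matrix.scale not in (Scale.log2, Scale.log2_quantile):
        raise ValueError(
            f"quantile_normalize expects a log2-scale matrix, got {matrix.scale.name}"
        )
    if matrix.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    values = matrix.values
    order = np.argsort(values, axis=0, kind="stable")
    reference = np.mean(np.take_along_axis(values, order, axis=0), axis=1)
    out = np.empty_like(values)
    n = matrix.n_genes
    for j in range(matrix.n_samples):
        col = values[:, j]
        idx = order[:, j]
        assigned = np.empty(n)
        assigned[idx] = reference
        # ties span a run of sorted positions: give each tied entry the
        # mean of the reference values over that run
        sorted_col = col[idx]
        start = 0
        while start < n:
            stop = start
            while stop + 1 < n and sorted_col[stop + 1] == sorted_col[start]:
                stop += 1
            if stop > start:
                assigned[idx[start : stop + 1]] = reference[start : stop + 1].mean()
            start = stop + 1
        out[:, j] = assigned
    return matrix.with_values(out, Scale.log2_quantile)


def batch_adjust(
    matrix: ExpressionMatrix,
    batches: Mapping[str, str] | Sequence[str],
    covariate_groups: Mapping[str, str] | Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Parametric empirical-Bayes location-scale batch adjustment (ComBat).

    Standardizes each gene (preserving covariate effects if given),
    estimates per-batch gene-wise location/scale, shrinks them toward
    moment-matched batch-level priors (normal prior for location,
    inverse-gamma for scale), removes the shrunken batch effects, and
    restores the pooled location/scale.

    Parameters
    ----------
    batches
        Batch label per sample: either a mapping ``sample_id -> label``
        covering all samples, or a sequence aligned with ``matrix.samples``.
    covariate_groups
        Optional categorical labels whose group effects are preserved
        during standardization (no covariates by default).
    """
    if matrix.scale != Scale.log2_quantile:
        raise ValueError(
            f"batch_adjust expects a quantile-normalized matrix, got {matrix.scale.name}"
        )
    batch_labels = _align_labels(batches, matrix.samples, "batch")
    uniq = _stable_unique(batch_labels)
    if len(uniq) < 2:
        raise ValueError("batch adjustment needs at least 2 batches")
    counts = {b: batch_labels.count(b) for b in uniq}
    small = [b for b, c in counts.items() if c < 2]
    if small:
        raise ValueError(f"each batch needs at least 2 samples; too small: {small}")

    cov_design = None
    if covariate_groups is not None:
        cov_labels = _align_labels(covariate_groups, matrix.samples, "covariate")
        cov_uniq = _stable_unique(cov_labels)
        if len(cov_uniq) > 1:
            # reference-coded dummies (first level dropped)
            cov_design = np.array(
                [[1.0 if lab == g else 0.0 for g in cov_uniq[1:]] for lab in cov_labels]
            )
            _check_confounding(batch_labels, cov_labels)

    adjusted = _combat(matrix.values, batch_labels, uniq, cov_design)
    return matrix.with_values(adjusted, Scale.log2_quantile_batchadj)


# ---------------------------------------------------------------------------
# ComBat internals


def _combat(
    Y: np.ndarray,
    batch_labels: Sequence[str],
    uniq: Sequence[str],
    cov_design: np.ndarray | None,
    conv: float = 1e-4,
) -> np.ndarray:
    n_genes, n_samples = Y.shape
    batch_idx = [np.array([i for i, b in enumerate(batch_labels) if b == lab]) for lab in uniq]
    n_batches = np.array([len(ix) for ix in batch_idx], dtype=float)

    batch_design = np.zeros((n_samples, len(uniq)))
    for k, ix in enumerate(batch_idx):
        batch_design[ix, k] = 1.0
    design = batch_design if cov_design is None else np.hstack([batch_design, cov_design])

    # gene-wise least squares fit of batch means (+ covariate effects)
    B_hat, *_ = np.linalg.lstsq(design, Y.T, rcond=None)  # (n_coef, n_genes)
    grand_mean = (n_batches / n_samples) @ B_hat[: len(uniq)]  # (n_genes,)
    resid = Y.T - design @ B_hat
    var_pooled = np.mean(resid**2, axis=0)  # (n_genes,)
    if np.any(var_pooled <= 0):
        raise ValueError("gene(s) with zero pooled variance; cannot standardize")

    stand_mean = np.tile(grand_mean, (n_samples, 1))
    if cov_design is not None:
        stand_mean = stand_mean + cov_design @ B_hat[len(uniq) :]
    sd = np.sqrt(var_pooled)
    Z = (Y.T - stand_mean) / sd  # (n_samples, n_genes)

    gamma_hat = np.array([Z[ix].mean(axis=0) for ix in batch_idx])  # (n_batch, n_genes)
    delta_hat = np.array([Z[ix].var(axis=0, ddof=1) for ix in batch_idx])

    gamma_bar = gamma_hat.mean(axis=1)
    t2 = gamma_hat.var(axis=1, ddof=1)
    a_prior = _aprior(delta_hat)
    b_prior = _bprior(delta_hat)

    Z_adj = np.empty_like(Z)
    for k, ix in enumerate(batch_idx):
        g_star, d_star = _it_sol(
            Z[ix], gamma_hat[k], delta_hat[k], gamma_bar[k], t2[k], a_prior[k], b_prior[k], conv
        )
        Z_adj[ix] = (Z[ix] - g_star) / np.sqrt(d_star)
    return (Z_adj * sd + stand_mean).T


def _aprior(delta_hat: np.ndarray) -> np.ndarray:
    m = delta_hat.mean(axis=1)
    s2 = delta_hat.var(axis=1, ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> np.ndarray:
    m = delta_hat.mean(axis=1)
    s2 = delta_hat.var(axis=1, ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(
    Z_batch: np.ndarray,
    g_hat: np.ndarray,
    d_hat: np.ndarray,
    g_bar: float,
    t2: float,
    a: float,
    b: float,
    conv: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the EB posterior-mean equations until relative convergence.

    The stopping rule mirrors the canonical implementation, including its
    signed denominator for the location term (negative entries are
    effectively ignored by the max), so results are bit-compatible with
    the reference at the same ``conv``.
    """
    n = Z_batch.shape[0]
    g_old = g_hat.copy()
    d_old = d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((Z_batch - g_new) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / g_old),
            np.max(np.abs(d_new - d_old) / d_old),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


# ---------------------------------------------------------------------------
# helpers


def _align_labels(
    labels: Mapping[str, str] | Sequence[str], samples: Sequence[str], what: str
) -> list[str]:
    if isinstance(labels, Mapping):
        missing = [s for s in samples if s not in labels]
        if missing:
            raise ValueError(f"{what} label missing for samples: {missing}")
        return [str(labels[s]) for s in samples]
    labels = [str(x) for x in labels]
    if len(labels) != len(samples):
        raise ValueError(
            f"{what} labels length {len(labels)} does not match {len(samples)} samples"
        )
    return labels


def _stable_unique(labels: Sequence[str]) -> list[str]:
    seen: list[str] = []
    for lab in labels:
        if lab not in seen:
            seen.append(lab)
    return seen


def _check_confounding(batch_labels: Sequence[str], cov_labels: Sequence[str]) -> None:
    # batch nested inside one covariate level == perfectly confounded
    per_batch: dict[str, set[str]] = {}
    for b, c in zip(batch_labels, cov_labels):
        per_batch.setdefault(b, set()).add(c)
    if all(len(v) == 1 for v in per_batch.values()) and len(
        {next(iter(v)) for v in per_batch.values()}
    ) == len(per_batch):
        raise ValueError("batch is perfectly confounded with the covariate")
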