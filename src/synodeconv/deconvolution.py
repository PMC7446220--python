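"""Cell-subset deconvolution via per-sample running-sum enrichment scores.

The contribution of a cell subset to a bulk sample is summarized by the
enrichment of its marker-gene signature within that sample's ranked gene
list: walking down the ranking, the running sum gains 1/|S| at each
signature gene and loses 1/(N-|S|) at each other gene, and the score is
the signed maximum deviation from zero (the classic unweighted
Kolmogorov-Smirnov GSEA statistic). Scores are compared between response
groups cross-sectionally (Welch t-test) and longitudinally (paired
t-test on within-patient week20 - week0 changes).

Because the score depends only on within-sample ranks, it is invariant
to positive affine transforms of a sample's expression — no cross-sample
standardization is applied or needed for the group contrasts, which
always compare the same fixed signature across samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSignature, SampleSheet

__all__ = [
    "EnrichmentScoreMatrix",
    "AssociationResult",
    "LongitudinalResult",
    "derive_signature",
    "rank_genes",
    "enrichment_score",
    "score_samples",
    "associate_with_response",
    "compare_longitudinal",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentScoreMatrix:
    """Samples x signatures matrix of enrichment scores, each in [-1, 1]."""

    samples: tuple[str, ...]
    signatures: tuple[str, ...]
    scores: np.ndarray  # (n_samples, n_signatures)

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (len(self.samples), len(self.signatures)):
            raise ValueError("scores shape does not match samples x signatures")
        if np.any(np.abs(scores) > 1 + 1e-12) or not np.all(np.isfinite(scores)):
            raise ValueError("enrichment scores must be finite and within [-1, 1]")
        object.__setattr__(self, "scores", scores)

    def score(self, sample: str, signature: str) -> float:
        return float(
            self.scores[self.samples.index(sample), self.signatures.index(signature)]
        )

    def column(self, signature: str) -> dict[str, float]:
        j = self.signatures.index(signature)
        return {s: float(self.scores[i, j]) for i, s in enumerate(self.samples)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=list(self.samples), columns=list(self.signatures)
        )


@dataclass(frozen=True)
class AssociationResult:
    """Group contrast of one signature's scores at one timepoint."""

    signature: str
    contrast: str
    mean_responders: float
    mean_nonresponders: float
    t_statistic: float
    p_value: float
    direction: str  # lower_in_responders | higher_in_responders | none

    def __post_init__(self) -> None:
        diff = self.mean_responders - self.mean_nonresponders
        expected = (
            "none" if diff == 0 else ("higher_in_responders" if diff > 0 else "lower_in_responders")
        )
        if self.direction != expected:
            raise ValueError(
                f"direction {self.direction!r} inconsistent with mean difference {diff}"
            )


@dataclass(frozen=True)
class LongitudinalResult:
    """Within-group paired week20 - week0 change plus the week-20 group contrast."""

    signature: str
    group: str
    n_pairs: int
    mean_change: float
    t_statistic: float
    p_value: float


# ---------------------------------------------------------------------------
# signature derivation


def derive_signature(
    mean_log2: np.ndarray | pd.DataFrame,
    genes: Sequence[str] | None = None,
    cell_types: Sequence[str] | None = None,
    *,
    target_type: str,
    n_top: int = 100,
    min_fc: float = 1.5,
) -> GeneSignature:
    """Top one-vs-rest overexpressed genes of one cell type.

    Genes are ranked by one-vs-rest log2 fold change — the target type's
    mean minus the maximum of every other type's mean — and the top
    ``n_top`` genes whose linear fold change exceeds ``min_fc`` are kept.
    Ties at any rank are broken by ascending gene id.

    Parameters
    ----------
    mean_log2
        Gene-by-type mean log2 expression, either a DataFrame (index =
        genes, columns = types) or an array with ``genes``/``cell_types``.
    """
    if isinstance(mean_log2, pd.DataFrame):
        frame = mean_log2
    else:
        frame = pd.DataFrame(np.asarray(mean_log2, float), index=list(genes), columns=list(cell_types))
    if frame.shape[1] < 2:
        raise ValueError("need at least 2 cell types to derive a one-vs-rest signature")
    if target_type not in frame.columns:
        raise KeyError(f"unknown cell type: {target_type!r}")
    others = frame.drop(columns=[target_type])
    log_fc = frame[target_type] - others.max(axis=1)
    min_log_fc = np.log2(min_fc)
    passing = log_fc[log_fc > min_log_fc]
    if passing.empty:
        raise ValueError(
            f"no gene exceeds min_fc={min_fc} for cell type {target_type!r}; "
            "signature would be empty"
        )
    ordered = passing.sort_index().sort_values(ascending=False, kind="stable")
    kept = ordered.index[:n_top]
    return GeneSignature(
        name=target_type,
        gene_ids=frozenset(kept),
        description=f"top one-vs-rest overexpressed genes (n_top={n_top}, min_fc={min_fc})",
    )


# ---------------------------------------------------------------------------
# ranking and enrichment score


def rank_genes(matrix: ExpressionMatrix, sample_id: str) -> tuple[str, ...]:
    """Genes sorted by descending expression in one sample; ties ascending by gene id."""
    col = matrix.column(sample_id)
    gene_arr = np.array(matrix.genes)
    # lexsort: last key is primary -> sort by -value, then gene id ascending
    order = np.lexsort((gene_arr, -col))
    return tuple(gene_arr[order])


def enrichment_score(
    ranked: Sequence[str],
    signature: GeneSignature,
    weights: Sequence[float] | None = None,
) -> float:
    """Signed maximum deviation from zero of the running-sum statistic.

    Walking down ``ranked``, the sum gains at each signature gene ("hit")
    and loses 1/(N-|S|) at each other gene ("miss"); unweighted hits gain
    1/|S|. The score is the running-sum value of largest absolute
    magnitude, always within [-1, 1]. An optional ``weights`` vector
    (aligned with ``ranked``) switches hit increments to
    |w_i| / sum(|w_hits|) for sensitivity analysis.
    """
    n = len(ranked)
    hits = np.fromiter((g in signature for g in ranked), dtype=bool, count=n)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError(f"signature {signature.name!r} has no genes in the ranked list")
    if n_hits == n:
        raise ValueError("signature covers the entire ranked list; score undefined")
    if weights is None:
        # integer-scaled running sum: hits add (N-|S|), misses subtract
        # |S|; dividing once by |S|(N-|S|) keeps the walk exact, so the
        # extremes are exactly +/-1 and |ES| <= 1 holds without clipping
        steps = np.where(hits, n - n_hits, -n_hits).astype(np.int64)
        running = np.cumsum(steps)
        peak = running[int(np.argmax(np.abs(running)))]
        return float(int(peak) / (n_hits * (n - n_hits)))
    w = np.abs(np.asarray(weights, dtype=float))
    if w.shape != (n,):
        raise ValueError("weights must align with the ranked list")
    total = w[hits].sum()
    if total <= 0:
        raise ValueError("weights of signature genes sum to zero")
    steps = np.empty(n)
    steps[hits] = w[hits] / total
    steps[~hits] = -1.0 / (n - n_hits)
    running = np.cumsum(steps)
    return float(np.clip(running[int(np.argmax(np.abs(running)))], -1.0, 1.0))


def score_samples(
    matrix: ExpressionMatrix,
    signatures: Sequence[GeneSignature],
    weighted: bool = False,
) -> EnrichmentScoreMatrix:
    """Enrichment score of every signature in every sample.

    Signature genes absent from the matrix are dropped (the drop count is
    logged); a signature with zero overlap is an error.
    """
    gene_set = set(matrix.genes)
    effective: list[GeneSignature] = []
    for sig in signatures:
        present = sig.gene_ids & gene_set
        if not present:
            raise ValueError(f"signature {sig.name!r} shares no genes with the matrix")
        dropped = len(sig.gene_ids) - len(present)
        if dropped:
            logger.info(
                "signature %r: %d/%d genes absent from matrix, dropped",
                sig.name,
                dropped,
                len(sig.gene_ids),
            )
        effective.append(GeneSignature(sig.name, frozenset(present), sig.description))

    scores = np.empty((matrix.n_samples, len(effective)))
    for i, sample in enumerate(matrix.samples):
        ranked = rank_genes(matrix, sample)
        w = None
        if weighted:
            col = matrix.column(sample)
            order = {g: v for g, v in zip(matrix.genes, col)}
            w = [order[g] for g in ranked]
        for j, sig in enumerate(effective):
            scores[i, j] = enrichment_score(ranked, sig, weights=w)
    return EnrichmentScoreMatrix(
        samples=matrix.samples,
        signatures=tuple(s.name for s in effective),
        scores=scores,
    )


# ---------------------------------------------------------------------------
# association with response


def _welch_groups(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if x.std() == 0 and y.std() == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def associate_with_response(
    scores: EnrichmentScoreMatrix,
    sheet: SampleSheet,
    timepoint: str = "week0",
    grouping: str = "responder_vs_non",
) -> list[AssociationResult]:
    """Welch t-test of scores between response groups at one timepoint.

    ``grouping`` is ``responder_vs_non`` (good+moderate vs none) or
    ``good_vs_rest`` (good vs moderate+none). Direction is labeled from
    the sign of (responder mean - non-responder mean).
    """
    if grouping == "responder_vs_non":
        pos = sheet.samples_where(timepoint=timepoint, responder=True)
        neg = sheet.samples_where(timepoint=timepoint, responder=False)
    elif grouping == "good_vs_rest":
        pos = sheet.samples_where(timepoint=timepoint, response="good")
        neg = sheet.samples_where(timepoint=timepoint, response=("moderate", "none"))
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    pos = tuple(s for s in pos if s in scores.samples)
    neg = tuple(s for s in neg if s in scores.samples)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError(
            f"need >=2 samples per group at {timepoint} (got {len(pos)} and {len(neg)})"
        )
    out: list[AssociationResult] = []
    for j, sig in enumerate(scores.signatures):
        col = scores.column(sig)
        x = np.array([col[s] for s in pos])
        y = np.array([col[s] for s in neg])
        t, p = _welch_groups(x, y)
        diff = x.mean() - y.mean()
        direction = (
            "none" if diff == 0 else ("higher_in_responders" if diff > 0 else "lower_in_responders")
        )
        out.append(
            AssociationResult(
                signature=sig,
                contrast=f"{grouping}@{timepoint}",
                mean_responders=float(x.mean()),
                mean_nonresponders=float(y.mean()),
                t_statistic=t,
                p_value=p,
                direction=direction,
            )
        )
    return out


def compare_longitudinal(
    scores: EnrichmentScoreMatrix,
    sheet: SampleSheet,
    signature: str,
) -> dict[str, object]:
    """Paired week20 - week0 change per response group, plus the week-20 group contrast.

    Returns a dict with key ``"paired"`` (list of
    :class:`LongitudinalResult`, one per response group with >=2 complete
    patient pairs) and key ``"week20_crosssectional"`` (the
    responder-vs-non association at week 20).
    """
    j = scores.signatures.index(signature)
    per_group: dict[str, list[float]] = {}
    n_complete = 0
    for patient in sheet.paired_patients():
        s0 = sheet.sample_of(patient, "week0")
        s20 = sheet.sample_of(patient, "week20")
        if s0 not in scores.samples or s20 not in scores.samples:
            continue
        n_complete += 1
        change = scores.scores[scores.samples.index(s20), j] - scores.scores[
            scores.samples.index(s0), j
        ]
        group = sheet.record(s0).response
        per_group.setdefault(group, []).append(float(change))
    if n_complete == 0:
        raise ValueError("no patient has scored samples at both timepoints")

    paired: list[LongitudinalResult] = []
    for group in sorted(per_group):
        diffs = np.array(per_group[group])
        if len(diffs) < 2:
            continue
        if diffs.std() == 0:
            t, p = (0.0, 1.0) if diffs.mean() == 0 else (float(np.sign(diffs.mean()) * np.inf), 0.0)
        else:
            with warnings.catch_warnings():
                # near-identical changes trip scipy's precision warning;
                # the degenerate exact cases are already handled above
                warnings.simplefilter("ignore", RuntimeWarning)
                res = stats.ttest_1samp(diffs, 0.0)
            t, p = float(res.statistic), float(res.pvalue)
        paired.append(
            LongitudinalResult(
                signature=signature,
                group=group,
                n_pairs=len(diffs),
                mean_change=float(diffs.mean()),
                t_statistic=t,
                p_value=p,
            )
        )
    cross = associate_with_response(scores, sheet, timepoint="week20")
    week20 = next(r for r in cross if r.signature == signature)
    return {"paired": paired, "week20_crosssectional": week20}
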