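"""Ground-truth synthetic data: reference profiles, bulk cohorts, GO annotations, Ct tables.

Bulk profiles are built as convex mixtures of cell-type reference
profiles on the linear intensity scale (intensities, not logs, are
additive across cells), then re-logged; measurement noise and batch
shifts are applied on the log2 scale. Every generator is deterministic
given its arguments plus ``seed``, and each generator draws from its own
RNG stream keyed by (seed, operation tag) so adding or removing one
generator call never perturbs another's output.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import (
    ExpressionMatrix,
    GOAnnotation,
    QpcrTable,
    SampleRecord,
    SampleSheet,
    Scale,
)

__all__ = [
    "ReferenceProfiles",
    "SyntheticTruth",
    "PlantedTerm",
    "generate_reference_profiles",
    "generate_cohort",
    "generate_go_annotation",
    "generate_qpcr",
]

BACKGROUND_MEAN = 7.0
BACKGROUND_SD = 1.0
DEFAULT_CELL_TYPES = ("TPH", "FIB_CD34", "FIB_THY1", "FIB_DN")


def _rng(seed: int, tag: str) -> np.random.Generator:
    """Independent stream per (seed, operation tag)."""
    digest = hashlib.sha256(tag.encode()).digest()
    tag_int = int.from_bytes(digest[:8], "big")
    return np.random.default_rng([int(seed), tag_int])


@dataclass(frozen=True)
class ReferenceProfiles:
    """Per-cell-type mean log2 expression with planted marker genes.

    Every marker gene of a type is strictly higher in that type than in
    any other (by the configured marker effect), and marker sets are
    pairwise disjoint.
    """

    cell_types: tuple[str, ...]
    genes: tuple[str, ...]
    mean_log2: np.ndarray  # (n_genes, n_types)
    marker_map: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        mean_log2 = np.asarray(self.mean_log2, dtype=float)
        if mean_log2.shape != (len(self.genes), len(self.cell_types)):
            raise ValueError("mean_log2 shape must be genes x cell types")
        if not np.all(np.isfinite(mean_log2)):
            raise ValueError("mean_log2 must be finite")
        object.__setattr__(self, "mean_log2", mean_log2)
        object.__setattr__(
            self,
            "marker_map",
            {t: frozenset(g) for t, g in dict(self.marker_map).items()},
        )
        all_markers: set[str] = set()
        for t, markers in self.marker_map.items():
            if all_markers & markers:
                raise ValueError("marker sets must be pairwise disjoint")
            all_markers |= markers

    def type_index(self, cell_type: str) -> int:
        return self.cell_types.index(cell_type)

    def profile(self, cell_type: str) -> np.ndarray:
        return self.mean_log2[:, self.type_index(cell_type)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.mean_log2, index=list(self.genes), columns=list(self.cell_types)
        )


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth of a synthetic cohort."""

    fractions: Mapping[str, Mapping[str, float]]  # sample -> type -> weight
    de_genes_up_resp: frozenset[str]
    de_genes_up_nonresp: frozenset[str]
    batch_shifts: Mapping[str, float]
    seed: int
    planted_go_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "fractions",
            {s: dict(f) for s, f in dict(self.fractions).items()},
        )
        for s, f in self.fractions.items():
            total = sum(f.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"fractions of sample {s!r} sum to {total}, not 1")
            if any(w < 0 or w > 1 for w in f.values()):
                raise ValueError(f"fractions of sample {s!r} outside [0, 1]")
        if self.de_genes_up_resp & self.de_genes_up_nonresp:
            raise ValueError("planted DE gene sets must be disjoint")


def generate_reference_profiles(
    n_genes: int,
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES,
    n_markers_per_type: int = 50,
    marker_effect: float = 2.0,
    seed: int = 0,
) -> ReferenceProfiles:
    """Reference profiles with ``n_markers_per_type`` planted markers per type.

    Background means are drawn from Normal(7, 1) on the log2 scale, and
    each marker gene gets ``+marker_effect`` in its own type only.
    """
    cell_types = tuple(cell_types)
    if marker_effect <= 0:
        raise ValueError("marker_effect must be positive")
    if n_markers_per_type * len(cell_types) > n_genes:
        raise ValueError(
            f"cannot place {n_markers_per_type} markers for each of "
            f"{len(cell_types)} types among {n_genes} genes"
        )
    rng = _rng(seed, "reference_profiles")
    genes = tuple(f"G{i:05d}" for i in range(n_genes))
    background = rng.normal(BACKGROUND_MEAN, BACKGROUND_SD, size=n_genes)
    mean_log2 = np.tile(background[:, None], (1, len(cell_types)))
    marker_ids = rng.choice(n_genes, size=n_markers_per_type * len(cell_types), replace=False)
    marker_map: dict[str, frozenset[str]] = {}
    for k, t in enumerate(cell_types):
        ids = marker_ids[k * n_markers_per_type : (k + 1) * n_markers_per_type]
        mean_log2[ids, k] += marker_effect
        marker_map[t] = frozenset(genes[i] for i in ids)
    return ReferenceProfiles(cell_types, genes, mean_log2, marker_map)


def _draw_fractions(
    rng: np.random.Generator,
    cell_types: Sequence[str],
    tph_type: str,
    tph_mean: float,
    tph_jitter: float,
) -> dict[str, float]:
    types = list(cell_types)
    if len(types) == 1:
        return {types[0]: 1.0}
    if tph_jitter > 0:
        a = tph_mean * tph_jitter
        b = (1.0 - tph_mean) * tph_jitter
        if a > 0 and b > 0:
            tph = float(np.clip(rng.beta(a, b), 0.0, 1.0))
        else:  # degenerate mean 0 or 1
            tph = tph_mean
    else:
        tph = tph_mean
    others = [t for t in types if t != tph_type]
    # residual mass spread over the remaining types (mildly random split)
    split = rng.dirichlet(np.full(len(others), 5.0))
    out = {tph_type: tph}
    for t, w in zip(others, split):
        out[t] = float((1.0 - tph) * w)
    return out


def generate_cohort(
    ref: ReferenceProfiles,
    n_responders: int = 8,
    n_nonresponders: int = 3,
    tph_fraction_resp: float = 0.05,
    tph_fraction_nonresp: float = 0.15,
    noise_sd: float = 0.3,
    n_de_genes: int = 20,
    de_effect: float = 1.0,
    batches: Mapping[str, float] | None = None,
    tph_type: str | None = None,
    tph_jitter: float = 50.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SampleSheet, SyntheticTruth]:
    """Paired two-timepoint bulk cohort with planted cell fractions and DE genes.

    Each patient contributes a week0 and a week20 sample sharing one set
    of mixing fractions (time-stable composition). The T_PH-like
    fraction is Beta-distributed around the group mean with concentration
    ``tph_jitter`` (0 disables jitter); the residual mass is spread over
    the remaining cell types. Planted DE genes get ``+de_effect`` in one
    response group at both timepoints; batch shifts are additive on the
    log2 scale and patients are assigned to batches round-robin.

    Returns ``(matrix, sheet, truth)`` with the matrix on the log2 scale.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    for name, frac in (("tph_fraction_resp", tph_fraction_resp), ("tph_fraction_nonresp", tph_fraction_nonresp)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {frac}")
    if tph_type is None:
        tph_type = ref.cell_types[0]
    if tph_type not in ref.cell_types:
        raise ValueError(f"unknown tph_type {tph_type!r}")
    rng = _rng(seed, "cohort")

    patients = [f"R{i + 1:02d}" for i in range(n_responders)] + [
        f"N{i + 1:02d}" for i in range(n_nonresponders)
    ]
    responses = [("good" if i % 2 == 0 else "moderate") for i in range(n_responders)] + [
        "none"
    ] * n_nonresponders

    batch_shifts = dict(batches) if batches else {"b1": 0.0}
    batch_labels = list(batch_shifts)
    patient_batch = {p: batch_labels[i % len(batch_labels)] for i, p in enumerate(patients)}

    # planted DE genes, drawn from non-marker background genes
    all_markers = set().union(*ref.marker_map.values()) if ref.marker_map else set()
    candidates = [g for g in ref.genes if g not in all_markers]
    if n_de_genes > len(candidates):
        raise ValueError("not enough non-marker genes to plant DE effects")
    de_pick = rng.choice(len(candidates), size=n_de_genes, replace=False)
    n_up_resp = n_de_genes // 2
    de_up_resp = frozenset(candidates[i] for i in de_pick[:n_up_resp])
    de_up_nonresp = frozenset(candidates[i] for i in de_pick[n_up_resp:])
    gene_index = {g: i for i, g in enumerate(ref.genes)}

    records: list[SampleRecord] = []
    fractions: dict[str, dict[str, float]] = {}
    columns: list[np.ndarray] = []
    sample_ids: list[str] = []
    linear_ref = np.exp2(ref.mean_log2)  # (genes, types)

    for patient, response in zip(patients, responses):
        responder = response in ("good", "moderate")
        mean = tph_fraction_resp if responder else tph_fraction_nonresp
        frac = _draw_fractions(rng, ref.cell_types, tph_type, mean, tph_jitter)
        weights = np.array([frac[t] for t in ref.cell_types])
        base = np.log2(linear_ref @ weights)
        shift = batch_shifts[patient_batch[patient]]
        de = np.zeros(len(ref.genes))
        planted = de_up_resp if responder else de_up_nonresp
        for g in planted:
            de[gene_index[g]] += de_effect
        for timepoint in ("week0", "week20"):
            sid = f"{patient}_{'wk0' if timepoint == 'week0' else 'wk20'}"
            noise = rng.normal(0.0, noise_sd, size=len(ref.genes)) if noise_sd > 0 else 0.0
            columns.append(base + shift + de + noise)
            sample_ids.append(sid)
            fractions[sid] = frac
            records.append(
                SampleRecord(
                    sample_id=sid,
                    patient_id=patient,
                    timepoint=timepoint,
                    response=response,
                    batch=patient_batch[patient],
                )
            )

    matrix = ExpressionMatrix(
        genes=ref.genes,
        samples=tuple(sample_ids),
        values=np.column_stack(columns),
        scale=Scale.log2,
    )
    sheet = SampleSheet(tuple(records))
    truth = SyntheticTruth(
        fractions=fractions,
        de_genes_up_resp=de_up_resp,
        de_genes_up_nonresp=de_up_nonresp,
        batch_shifts=batch_shifts if batches else {},
        seed=seed,
    )
    return matrix, sheet, truth


@dataclass(frozen=True)
class PlantedTerm:
    """Specification of one GO term constructed to be enriched.

    ``overlap_fraction`` of the term's members are taken from
    ``de_genes``; the rest come from the remaining universe.
    """

    name: str
    de_genes: frozenset[str]
    size: int = 10
    overlap_fraction: float = 0.8

    def __post_init__(self) -> None:
        object.__setattr__(self, "de_genes", frozenset(self.de_genes))


def generate_go_annotation(
    genes: Sequence[str],
    n_terms: int = 50,
    term_size_range: tuple[int, int] = (5, 40),
    planted: Sequence[PlantedTerm] = (),
    seed: int = 0,
) -> tuple[GOAnnotation, tuple[str, ...]]:
    """Random GO annotation plus terms planted to overlap DE gene sets.

    Returns ``(annotation, planted_term_ids)``. ``n_terms`` counts the
    random (non-planted) terms.
    """
    universe = list(genes)
    lo, hi = term_size_range
    if hi > len(universe):
        raise ValueError("term sizes must not exceed the universe size")
    rng = _rng(seed, "go_annotation")
    terms: dict[str, tuple[str, frozenset[str]]] = {}

    planted_ids: list[str] = []
    for i, spec in enumerate(planted):
        n_de = int(round(spec.size * spec.overlap_fraction))
        n_bg = spec.size - n_de
        de_pool = sorted(spec.de_genes & set(universe))
        bg_pool = sorted(set(universe) - spec.de_genes)
        if n_de > len(de_pool) or n_bg > len(bg_pool):
            raise ValueError(
                f"planted term {spec.name!r}: cannot draw {n_de} DE + {n_bg} background genes"
            )
        members = list(rng.choice(de_pool, size=n_de, replace=False)) + list(
            rng.choice(bg_pool, size=n_bg, replace=False)
        )
        tid = f"GO:P{i + 1:04d}"
        terms[tid] = (spec.name, frozenset(members))
        planted_ids.append(tid)

    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        terms[f"GO:R{i + 1:04d}"] = (f"random term {i + 1}", frozenset(members))

    return GOAnnotation(terms), tuple(planted_ids)


def generate_qpcr(
    expr: ExpressionMatrix,
    target_genes: Sequence[str],
    endogenous_gene: str,
    slope: float = -1.0,
    intercept: float = 35.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> QpcrTable:
    """Ct table linearly linked to log2 expression.

    Ct = intercept + slope * log2_expression + Normal(0, noise_sd), per
    sample per gene, with the endogenous control measured in every
    sample. ``slope`` must be negative (higher expression -> lower Ct).
    """
    if slope >= 0:
        raise ValueError("slope must be negative (higher expression, lower Ct)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    genes = list(dict.fromkeys(list(target_genes) + [endogenous_gene]))
    for g in genes:
        if g not in expr.genes:
            raise KeyError(f"gene {g!r} not present in the expression matrix")
    rng = _rng(seed, "qpcr")
    rows: list[tuple[str, str, float]] = []
    for s in expr.samples:
        col = expr.column(s)
        for g in genes:
            value = intercept + slope * col[expr.gene_index(g)]
            if noise_sd > 0:
                value += rng.normal(0.0, noise_sd)
            rows.append((s, g, float(value)))
    return QpcrTable(tuple(rows), endogenous_gene=endogenous_gene)
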