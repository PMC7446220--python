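"""Readers, writers, and domain types for the tabular formats the pipeline touches.

All on-disk formats are plain tab-delimited text: expression matrices
(genes x samples), sample sheets, GMT gene-set files, GO annotations
(TSV or GMT), and qPCR Ct tables. Readers validate and reject malformed
input rather than coercing it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Scale",
    "ExpressionMatrix",
    "SampleSheet",
    "GeneSignature",
    "GOAnnotation",
    "QpcrTable",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_go_annotation",
    "write_go_annotation",
    "read_qpcr_table",
    "write_qpcr_table",
]


class Scale(enum.IntEnum):
    """Processing stage of an expression matrix; transitions only move forward."""

    raw = 0
    log2 = 1
    log2_quantile = 2
    log2_quantile_batchadj = 3


_RESPONSE_LABELS = ("good", "moderate", "none")
_TIMEPOINTS = ("week0", "week20")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene-by-sample expression values with scale provenance.

    Parameters
    ----------
    genes
        Ordered unique gene identifiers (opaque, case-sensitive strings).
    samples
        Ordered unique sample identifiers.
    values
        ``(n_genes, n_samples)`` float array; all entries must be finite.
    scale
        Member of :class:`Scale` recording the processing stage.
    """

    genes: tuple[str, ...]
    samples: tuple[str, ...]
    values: np.ndarray
    scale: Scale

    def __post_init__(self) -> None:
        genes = tuple(str(g) for g in self.genes)
        samples = tuple(str(s) for s in self.samples)
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "samples", samples)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape != (len(genes), len(samples)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        object.__setattr__(self, "values", values)
        for name, ids in (("gene", genes), ("sample", samples)):
            if len(set(ids)) != len(ids):
                dup = _first_duplicate(ids)
                raise ValueError(f"duplicate {name} id: {dup!r}")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must all be finite")
        if not isinstance(self.scale, Scale):
            object.__setattr__(self, "scale", Scale[str(self.scale)])

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene id: {gene!r}") from None

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample!r}") from None

    def column(self, sample: str) -> np.ndarray:
        return self.values[:, self.sample_index(sample)]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return ExpressionMatrix(
            self.genes, tuple(sample_ids), self.values[:, idx], self.scale
        )

    def with_values(self, values: np.ndarray, scale: Scale) -> "ExpressionMatrix":
        """Return a copy with new values at a new (never earlier) scale."""
        if scale < self.scale:
            raise ValueError(
                f"scale may not move backwards: {self.scale.name} -> {scale.name}"
            )
        return ExpressionMatrix(self.genes, self.samples, values, scale)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.genes), columns=list(self.samples)
        )


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    patient_id: str
    timepoint: str
    response: str
    batch: str

    @property
    def responder_flag(self) -> bool:
        return self.response in ("good", "moderate")


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample clinical/technical annotations.

    ``responder_flag`` is always derived from ``response`` (good or moderate
    count as responders), never read from disk.
    """

    records: tuple[SampleRecord, ...]

    def __post_init__(self) -> None:
        records = tuple(self.records)
        object.__setattr__(self, "records", records)
        seen: set[str] = set()
        pairs: set[tuple[str, str]] = set()
        for r in records:
            if r.sample_id in seen:
                raise ValueError(f"duplicate sample id: {r.sample_id!r}")
            seen.add(r.sample_id)
            if r.timepoint not in _TIMEPOINTS:
                raise ValueError(
                    f"unknown timepoint {r.timepoint!r} for sample {r.sample_id!r}"
                    f" (expected one of {_TIMEPOINTS})"
                )
            if r.response not in _RESPONSE_LABELS:
                raise ValueError(
                    f"unknown response label {r.response!r} for sample {r.sample_id!r}"
                    f" (expected one of {_RESPONSE_LABELS})"
                )
            key = (r.patient_id, r.timepoint)
            if key in pairs:
                raise ValueError(
                    f"patient {r.patient_id!r} has more than one sample at {r.timepoint}"
                )
            pairs.add(key)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(r.sample_id for r in self.records)

    def record(self, sample_id: str) -> SampleRecord:
        for r in self.records:
            if r.sample_id == sample_id:
                return r
        raise KeyError(f"unknown sample id: {sample_id!r}")

    def samples_where(
        self,
        timepoint: str | None = None,
        responder: bool | None = None,
        response: str | Iterable[str] | None = None,
    ) -> tuple[str, ...]:
        if isinstance(response, str):
            response = (response,)
        out = []
        for r in self.records:
            if timepoint is not None and r.timepoint != timepoint:
                continue
            if responder is not None and r.responder_flag != responder:
                continue
            if response is not None and r.response not in response:
                continue
            out.append(r.sample_id)
        return tuple(out)

    def batches(self) -> dict[str, str]:
        return {r.sample_id: r.batch for r in self.records}

    def paired_patients(self) -> tuple[str, ...]:
        """Patients with samples at both timepoints, in sheet order."""
        by_patient: dict[str, set[str]] = {}
        order: list[str] = []
        for r in self.records:
            if r.patient_id not in by_patient:
                order.append(r.patient_id)
            by_patient.setdefault(r.patient_id, set()).add(r.timepoint)
        return tuple(p for p in order if by_patient[p] == set(_TIMEPOINTS))

    def sample_of(self, patient_id: str, timepoint: str) -> str:
        for r in self.records:
            if r.patient_id == patient_id and r.timepoint == timepoint:
                return r.sample_id
        raise KeyError(f"no sample for patient {patient_id!r} at {timepoint}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "patient_id": [r.patient_id for r in self.records],
                "timepoint": [r.timepoint for r in self.records],
                "response": [r.response for r in self.records],
                "responder_flag": [r.responder_flag for r in self.records],
                "batch": [r.batch for r in self.records],
            }
        )


@dataclass(frozen=True)
class GeneSignature:
    """A named, non-empty gene set marking one cell subset."""

    name: str
    gene_ids: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", frozenset(self.gene_ids))
        if not self.gene_ids:
            raise ValueError(f"gene signature {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene: str) -> bool:
        return gene in self.gene_ids


@dataclass(frozen=True)
class GOAnnotation:
    """Mapping of term id -> (term name, gene set)."""

    terms: Mapping[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        terms = {
            str(tid): (str(name), frozenset(genes))
            for tid, (name, genes) in dict(self.terms).items()
        }
        for tid, (_, genes) in terms.items():
            if not genes:
                raise ValueError(f"GO term {tid!r} has no genes")
        object.__setattr__(self, "terms", terms)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.items())

    def name_of(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def genes_of(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]


@dataclass(frozen=True)
class QpcrTable:
    """Long-format Ct measurements plus the endogenous-control gene id.

    The endogenous gene must be measured for every sample that appears in
    the table; Ct values are finite and positive cycles.
    """

    rows: tuple[tuple[str, str, float], ...]  # (sample_id, gene_id, ct)
    endogenous_gene: str

    def __post_init__(self) -> None:
        rows = tuple((str(s), str(g), float(c)) for s, g, c in self.rows)
        object.__setattr__(self, "rows", rows)
        for s, g, c in rows:
            if not np.isfinite(c) or c <= 0:
                raise ValueError(f"Ct for ({s}, {g}) must be finite and positive, got {c}")
        samples = {s for s, _, _ in rows}
        with_endo = {s for s, g, _ in rows if g == self.endogenous_gene}
        missing = samples - with_endo
        if missing:
            raise ValueError(
                "endogenous gene "
                f"{self.endogenous_gene!r} missing for samples: {sorted(missing)}"
            )

    @property
    def sample_ids(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s, _, _ in self.rows:
            if s not in seen:
                seen.append(s)
        return tuple(seen)

    def ct(self, sample_id: str, gene_id: str) -> float:
        """Mean Ct for (sample, gene); technical replicates averaged on the Ct scale."""
        vals = [c for s, g, c in self.rows if s == sample_id and g == gene_id]
        if not vals:
            raise KeyError(f"no Ct measurement for ({sample_id!r}, {gene_id!r})")
        return float(np.mean(vals))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["sample_id", "gene_id", "ct"])


# ---------------------------------------------------------------------------
# helpers


def _first_duplicate(ids: Sequence[str]) -> str:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            return i
        seen.add(i)
    raise AssertionError("no duplicate present")


def _read_tsv_lines(path: str | Path) -> list[list[str]]:
    lines: list[list[str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n").rstrip("\r")
            if line == "":
                continue
            lines.append(line.split("\t"))
    if not lines:
        raise ValueError(f"{path}: file is empty")
    return lines


# ---------------------------------------------------------------------------
# expression matrix


def read_expression_tsv(path: str | Path, scale: Scale | str = Scale.log2) -> ExpressionMatrix:
    """Read a tab-delimited gene-by-sample matrix.

    First column holds gene ids, header row holds sample ids. Duplicate
    ids, non-numeric cells, and ragged rows are rejected.
    """
    if isinstance(scale, str):
        scale = Scale[scale]
    lines = _read_tsv_lines(path)
    header = lines[0]
    samples = header[1:]
    if not samples:
        raise ValueError(f"{path}: header has no sample columns")
    genes: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for ln, fields in enumerate(lines[1:], start=2):
        if len(fields) != len(header):
            raise ValueError(
                f"{path}:{ln}: ragged row ({len(fields)} fields, expected {len(header)})"
            )
        gene = fields[0]
        if gene in seen:
            raise ValueError(f"{path}:{ln}: duplicated gene row {gene!r}")
        seen.add(gene)
        try:
            row = [float(x) for x in fields[1:]]
        except ValueError:
            bad = next(x for x in fields[1:] if not _is_number(x))
            raise ValueError(f"{path}:{ln}: non-numeric cell {bad!r} in row {gene!r}") from None
        genes.append(gene)
        rows.append(row)
    if not genes:
        raise ValueError(f"{path}: no gene rows")
    return ExpressionMatrix(tuple(genes), tuple(samples), np.array(rows, dtype=float), scale)


def _is_number(x: str) -> bool:
    try:
        float(x)
        return True
    except ValueError:
        return False


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.samples) + "\n")
        for i, gene in enumerate(matrix.genes):
            vals = "\t".join(repr(float(v)) for v in matrix.values[i])
            fh.write(f"{gene}\t{vals}\n")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Read gene signatures in GMT dialect: name TAB description TAB gene ids."""
    out: list[GeneSignature] = []
    lines = _read_tsv_lines(path)
    for ln, fields in enumerate(lines, start=1):
        if len(fields) < 3:
            raise ValueError(f"{path}:{ln}: GMT line needs >=3 fields, got {len(fields)}")
        name, desc, *genes = fields
        genes = [g for g in genes if g != ""]
        if not genes:
            raise ValueError(f"{path}:{ln}: gene set {name!r} is empty")
        out.append(GeneSignature(name=name, gene_ids=frozenset(genes), description=desc))
    return out


def write_gmt(signatures: Sequence[GeneSignature], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sig in signatures:
            genes = "\t".join(sorted(sig.gene_ids))
            fh.write(f"{sig.name}\t{sig.description}\t{genes}\n")


# ---------------------------------------------------------------------------
# sample sheet

_SHEET_COLUMNS = ("sample_id", "patient_id", "timepoint", "response", "batch")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    lines = _read_tsv_lines(path)
    header = lines[0]
    missing = [c for c in _SHEET_COLUMNS if c not in header]
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {missing}")
    col = {c: header.index(c) for c in _SHEET_COLUMNS}
    records = []
    for ln, fields in enumerate(lines[1:], start=2):
        if len(fields) != len(header):
            raise ValueError(f"{path}:{ln}: ragged row")
        records.append(
            SampleRecord(
                sample_id=fields[col["sample_id"]],
                patient_id=fields[col["patient_id"]],
                timepoint=fields[col["timepoint"]],
                response=fields[col["response"]],
                batch=fields[col["batch"]],
            )
        )
    return SampleSheet(tuple(records))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_SHEET_COLUMNS) + "\n")
        for r in sheet.records:
            fh.write(
                f"{r.sample_id}\t{r.patient_id}\t{r.timepoint}\t{r.response}\t{r.batch}\n"
            )


# ---------------------------------------------------------------------------
# GO annotation


def read_go_annotation(path: str | Path) -> GOAnnotation:
    """Read a GO annotation from TSV (term_id, term_name, gene_id rows) or GMT."""
    lines = _read_tsv_lines(path)
    header = lines[0]
    if header[:3] == ["term_id", "term_name", "gene_id"]:
        terms: dict[str, tuple[str, set[str]]] = {}
        for ln, fields in enumerate(lines[1:], start=2):
            if len(fields) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 fields")
            tid, tname, gene = fields
            if tid in terms and terms[tid][0] != tname:
                raise ValueError(f"{path}:{ln}: term {tid!r} has conflicting names")
            terms.setdefault(tid, (tname, set()))[1].add(gene)
        return GOAnnotation({t: (n, frozenset(g)) for t, (n, g) in terms.items()})
    # fall back to GMT dialect
    sigs = read_gmt(path)
    ids = [s.name for s in sigs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate term id {_first_duplicate(ids)!r}")
    return GOAnnotation({s.name: (s.description, s.gene_ids) for s in sigs})


def write_go_annotation(annotation: GOAnnotation, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_id\tterm_name\tgene_id\n")
        for tid in sorted(annotation.terms):
            name, genes = annotation.terms[tid]
            for g in sorted(genes):
                fh.write(f"{tid}\t{name}\t{g}\n")


# ---------------------------------------------------------------------------
# qPCR table


def read_qpcr_table(path: str | Path, endogenous_gene: str) -> QpcrTable:
    lines = _read_tsv_lines(path)
    header = lines[0]
    required = ("sample_id", "gene_id", "ct")
    missing = [c for c in required if c not in header]
    if missing:
        raise ValueError(f"{path}: Ct table missing columns {missing}")
    col = {c: header.index(c) for c in required}
    rows = []
    for ln, fields in enumerate(lines[1:], start=2):
        if len(fields) != len(header):
            raise ValueError(f"{path}:{ln}: ragged row")
        try:
            ct = float(fields[col["ct"]])
        except ValueError:
            raise ValueError(f"{path}:{ln}: non-numeric Ct {fields[col['ct']]!r}") from None
        rows.append((fields[col["sample_id"]], fields[col["gene_id"]], ct))
    return QpcrTable(tuple(rows), endogenous_gene=endogenous_gene)


def write_qpcr_table(table: QpcrTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgene_id\tct\n")
        for s, g, c in table.rows:
            fh.write(f"{s}\t{g}\t{repr(float(c))}\n")
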