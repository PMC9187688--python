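"""Typed data model and I/O for single-cell circRNA count data.

Internal genomic coordinates are 0-based half-open throughout.  The rendered
form of a circRNA locus (``chrom:start+1-end``) and BED export follow each
format's own convention, so the arithmetic inside the package never has to
guess a base.

The per-cell BSJ (back-spliced junction) input is a simplified 7-column TSV
(``circ_id  chrom  start  end  strand  gene_id  bsj_reads``) rather than any
particular detector's native dialect; detector-specific adapters can map onto
it.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .errors import BsjParseError, ConsistencyError, MatrixFormatError

STRANDS = frozenset({"+", "-", "."})
TUMOR_STATUSES = frozenset({"normal", "tumor", "unknown"})

BSJ_COLUMNS = ("circ_id", "chrom", "start", "end", "strand", "gene_id", "bsj_reads")


@dataclass(frozen=True)
class CircRNARecord:
    """A circRNA locus; ``start``/``end`` are 0-based half-open."""

    circ_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.circ_id}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"{self.circ_id}: invalid strand {self.strand!r}")

    @property
    def coord(self) -> str:
        """Rendered 1-based inclusive form, e.g. ``chr1:100-200``."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


def coord_to_string(chrom: str, start: int, end: int) -> str:
    """Render a 0-based half-open interval as ``chrom:start+1-end``."""
    return f"{chrom}:{start + 1}-{end}"


def coord_from_string(coord: str) -> tuple[str, int, int]:
    """Inverse of :func:`coord_to_string`; returns (chrom, start, end) 0-based half-open."""
    chrom, _, span = coord.rpartition(":")
    if not chrom:
        raise ValueError(f"malformed coordinate string {coord!r}")
    first, _, last = span.partition("-")
    try:
        start1, end = int(first), int(last)
    except ValueError as exc:
        raise ValueError(f"malformed coordinate string {coord!r}") from exc
    return chrom, start1 - 1, end


@dataclass(frozen=True)
class CellAnnotation:
    """Per-cell metadata: batch, tissue, curated cell type, developmental stage."""

    cell_id: str
    study_id: str = ""
    tissue: str = ""
    cell_type: str = ""
    stage: str = ""
    tumor_status: str = "unknown"
    mapped_reads: int | None = None

    def __post_init__(self) -> None:
        if self.tumor_status not in TUMOR_STATUSES:
            raise ValueError(
                f"{self.cell_id}: tumor_status must be one of {sorted(TUMOR_STATUSES)}"
            )
        if self.mapped_reads is not None and self.mapped_reads < 0:
            raise ValueError(f"{self.cell_id}: mapped_reads must be non-negative")


def _check_unique(labels: Sequence[str], what: str) -> None:
    if len(set(labels)) != len(labels):
        seen: set[str] = set()
        dups = sorted({x for x in labels if x in seen or seen.add(x)})
        raise ValueError(f"duplicate {what} labels: {dups[:5]}")


@dataclass
class CountMatrix:
    """Sparse non-negative integer matrix of features x cells.

    ``feature_kind`` is ``"gene"`` or ``"circ"``; for circRNA matrices the
    entries are raw BSJ read counts.
    """

    values: sp.csr_matrix
    feature_ids: list[str]
    cell_ids: list[str]
    feature_kind: str = "gene"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("gene", "circ"):
            raise ValueError(f"feature_kind must be 'gene' or 'circ', got {self.feature_kind!r}")
        values = sp.csr_matrix(self.values)
        if values.nnz:
            data = values.data
            if data.min() < 0:
                raise ValueError("count matrix entries must be non-negative")
            if not np.issubdtype(data.dtype, np.integer):
                if not np.allclose(data, np.round(data)):
                    raise ValueError("count matrix entries must be integral")
                values = values.astype(np.int64)
        elif not np.issubdtype(values.dtype, np.integer):
            values = values.astype(np.int64)
        self.values = values
        self.feature_ids = list(self.feature_ids)
        self.cell_ids = list(self.cell_ids)
        if values.shape != (len(self.feature_ids), len(self.cell_ids)):
            raise ValueError(
                f"label/shape mismatch: matrix {values.shape}, "
                f"{len(self.feature_ids)} features x {len(self.cell_ids)} cells"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.cell_ids, "cell")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def cell_sums(self) -> np.ndarray:
        """Per-cell total counts (library size for gene matrices)."""
        return np.asarray(self.values.sum(axis=0)).ravel()

    def feature_sums(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=1)).ravel()

    def cell_nnz(self) -> np.ndarray:
        """Number of detected (count > 0) features per cell."""
        return self.values.getnnz(axis=0)

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep, dtype=bool)
        if keep.shape != (self.n_cells,):
            raise ValueError(f"mask length {keep.size} != number of cells {self.n_cells}")
        idx = np.flatnonzero(keep)
        return CountMatrix(
            self.values[:, idx],
            self.feature_ids,
            [self.cell_ids[i] for i in idx],
            self.feature_kind,
        )

    def subset_features(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep, dtype=bool)
        if keep.shape != (self.n_features,):
            raise ValueError(f"mask length {keep.size} != number of features {self.n_features}")
        idx = np.flatnonzero(keep)
        return CountMatrix(
            self.values[idx, :],
            [self.feature_ids[i] for i in idx],
            self.cell_ids,
            self.feature_kind,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.toarray(), index=self.feature_ids, columns=self.cell_ids
        )


# ---------------------------------------------------------------------------
# BSJ tables


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def parse_bsj_table(path, coordinate_base: int = 1) -> list[tuple[CircRNARecord, int]]:
    """Parse one cell's 7-column BSJ TSV into (record, read count) pairs.

    ``coordinate_base`` declares the convention of the ``start`` column in the
    file (1 for 1-based inclusive as detectors usually print, 0 for 0-based
    half-open); coordinates are converted to the internal 0-based half-open
    form.  Duplicate ``circ_id`` rows are summed when their coordinates agree
    and rejected otherwise.
    """
    if coordinate_base not in (0, 1):
        raise ValueError("coordinate_base must be 0 or 1")
    out: dict[str, tuple[CircRNARecord, int]] = {}
    with _open_text(path) as fh:
        header = fh.readline()
        if not header:
            raise BsjParseError(f"{path}: empty file (missing header)")
        cols = header.rstrip("\n").split("\t")
        if set(BSJ_COLUMNS) - set(cols):
            missing = sorted(set(BSJ_COLUMNS) - set(cols))
            raise BsjParseError(f"{path}: header missing columns {missing}")
        pos = {c: cols.index(c) for c in BSJ_COLUMNS}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise BsjParseError(f"line {lineno}: expected {len(cols)} fields, got {len(fields)}")
            try:
                circ_id = fields[pos["circ_id"]]
                chrom = fields[pos["chrom"]]
                start = int(fields[pos["start"]]) - coordinate_base
                end = int(fields[pos["end"]])
                strand = fields[pos["strand"]]
                gene_id = fields[pos["gene_id"]]
                reads = int(fields[pos["bsj_reads"]])
            except ValueError as exc:
                raise BsjParseError(f"line {lineno}: {exc}") from exc
            if reads < 0:
                raise BsjParseError(f"line {lineno}: negative bsj_reads {reads}")
            try:
                rec = CircRNARecord(circ_id, chrom, start, end, strand, gene_id)
            except ValueError as exc:
                raise BsjParseError(f"line {lineno}: {exc}") from exc
            if circ_id in out:
                prev, prev_reads = out[circ_id]
                if prev != rec:
                    raise BsjParseError(
                        f"line {lineno}: duplicate circ_id {circ_id!r} with conflicting records"
                    )
                out[circ_id] = (prev, prev_reads + reads)
            else:
                out[circ_id] = (rec, reads)
    return list(out.values())


def assemble_bsj_matrix(
    tables: Mapping[str, Sequence[tuple[CircRNARecord, int]]],
) -> tuple[CountMatrix, list[CircRNARecord]]:
    """Union per-cell BSJ tables into one circ x cell count matrix.

    The feature set is the union of circ ids across cells (first-appearance
    order); absent (circ, cell) pairs are zero.  A circ id carrying different
    coordinate records in different cells is a consistency error.
    """
    records: dict[str, CircRNARecord] = {}
    conflicts: set[str] = set()
    cell_ids = list(tables)
    for cell in cell_ids:
        for rec, _reads in tables[cell]:
            prev = records.get(rec.circ_id)
            if prev is None:
                records[rec.circ_id] = rec
            elif prev != rec:
                conflicts.add(rec.circ_id)
    if conflicts:
        raise ConsistencyError(
            f"conflicting coordinates for circ ids: {sorted(conflicts)[:10]}"
        )
    feature_index = {cid: i for i, cid in enumerate(records)}
    rows: list[int] = []
    cols: list[int] = []
    vals: list[int] = []
    for j, cell in enumerate(cell_ids):
        for rec, reads in tables[cell]:
            rows.append(feature_index[rec.circ_id])
            cols.append(j)
            vals.append(reads)
    mat = sp.coo_matrix(
        (vals, (rows, cols)), shape=(len(records), len(cell_ids)), dtype=np.int64
    ).tocsr()
    cm = CountMatrix(mat, list(records), cell_ids, feature_kind="circ")
    return cm, list(records.values())


# ---------------------------------------------------------------------------
# Matrix I/O

MTX_FILE = "matrix.mtx"
FEATURES_FILE = "features.tsv"
CELLS_FILE = "cells.tsv"


def write_matrix(matrix: CountMatrix, path, format: str = "mtx") -> None:
    """Write a count matrix as MTX-with-sidecars (``path`` is a directory) or TSV."""
    if format == "mtx":
        outdir = Path(path)
        outdir.mkdir(parents=True, exist_ok=True)
        buf = io.BytesIO()
        mmwrite(buf, matrix.values.tocoo(), field="integer")
        (outdir / MTX_FILE).write_bytes(buf.getvalue())
        (outdir / FEATURES_FILE).write_text("".join(f"{f}\n" for f in matrix.feature_ids))
        (outdir / CELLS_FILE).write_text("".join(f"{c}\n" for c in matrix.cell_ids))
    elif format == "tsv":
        matrix.to_frame().to_csv(path, sep="\t", index_label="feature_id")
    else:
        raise ValueError(f"unknown matrix format {format!r}")


def _read_labels(path) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_matrix(path, format: str = "mtx", feature_kind: str = "gene") -> CountMatrix:
    """Inverse of :func:`write_matrix`; validates bounds, dtype and labels."""
    if format == "mtx":
        indir = Path(path)
        mtx_path = indir / MTX_FILE
        if not mtx_path.exists() and (indir / (MTX_FILE + ".gz")).exists():
            mtx_path = indir / (MTX_FILE + ".gz")
        try:
            with _open_text(mtx_path, "rb" if mtx_path.suffix == ".gz" else "rb") as fh:
                if mtx_path.suffix == ".gz":
                    fh = io.BytesIO(fh.read())
                mat = mmread(fh)
        except ValueError as exc:
            raise MatrixFormatError(f"{mtx_path}: {exc}") from exc
        mat = sp.csr_matrix(mat)
        if mat.nnz and not np.issubdtype(mat.data.dtype, np.integer):
            if not np.allclose(mat.data, np.round(mat.data)):
                raise MatrixFormatError(f"{mtx_path}: non-integer entries in count matrix")
            mat = mat.astype(np.int64)
        features = _read_labels(indir / FEATURES_FILE)
        cells = _read_labels(indir / CELLS_FILE)
        if mat.shape != (len(features), len(cells)):
            raise MatrixFormatError(
                f"{mtx_path}: declared shape {mat.shape} does not match sidecar labels "
                f"({len(features)} features, {len(cells)} cells)"
            )
        try:
            return CountMatrix(mat, features, cells, feature_kind)
        except ValueError as exc:
            raise MatrixFormatError(str(exc)) from exc
    if format == "tsv":
        with _open_text(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        cell_cols = header[1:]
        if len(set(cell_cols)) != len(cell_cols):
            raise MatrixFormatError(f"{path}: repeated cell column labels")
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy()
        if values.size and not np.allclose(values, np.round(values)):
            raise MatrixFormatError(f"{path}: non-integer entries in count matrix")
        try:
            return CountMatrix(
                sp.csr_matrix(values.astype(np.int64)),
                [str(i) for i in df.index],
                [str(c) for c in df.columns],
                feature_kind,
            )
        except ValueError as exc:
            raise MatrixFormatError(str(exc)) from exc
    raise ValueError(f"unknown matrix format {format!r}")


def matrix_io(matrix, path, direction: str, format: str = "mtx", feature_kind: str = "gene"):
    """Dispatcher: ``direction='write'`` writes ``matrix``; ``'read'`` loads from ``path``."""
    if direction == "write":
        return write_matrix(matrix, path, format=format)
    if direction == "read":
        return read_matrix(path, format=format, feature_kind=feature_kind)
    raise ValueError(f"direction must be 'read' or 'write', got {direction!r}")


def export_bed(
    records: Iterable[CircRNARecord], totals: Mapping[str, int], path
) -> None:
    """BED6 export: name = circ_id, score = total BSJ reads capped at 1000."""
    with open(path, "w") as fh:
        for rec in records:
            score = min(int(totals.get(rec.circ_id, 0)), 1000)
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.circ_id}\t{score}\t{rec.strand}\n"
            )


# ---------------------------------------------------------------------------
# Cell annotations

ANNOTATION_COLUMNS = (
    "cell_id",
    "study_id",
    "tissue",
    "cell_type",
    "stage",
    "tumor_status",
    "mapped_reads",
)


def write_annotations(annotations: Iterable[CellAnnotation], path) -> None:
    rows = [
        {
            "cell_id": a.cell_id,
            "study_id": a.study_id,
            "tissue": a.tissue,
            "cell_type": a.cell_type,
            "stage": a.stage,
            "tumor_status": a.tumor_status,
            "mapped_reads": "" if a.mapped_reads is None else a.mapped_reads,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> list[CellAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise MatrixFormatError(f"{path}: annotation table missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        mapped = getattr(row, "mapped_reads")
        out.append(
            CellAnnotation(
                cell_id=row.cell_id,
                study_id=row.study_id,
                tissue=row.tissue,
                cell_type=row.cell_type,
                stage=row.stage,
                tumor_status=row.tumor_status or "unknown",
                mapped_reads=None if mapped in ("", "nan") else int(float(mapped)),
            )
        )
    _check_unique([a.cell_id for a in out], "cell")
    return out
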