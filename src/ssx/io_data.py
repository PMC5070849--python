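"""Reading, writing and assembly of expression matrices and gene lists.

Expression matrices are tab-separated text: one header row of time-point
labels, one gene identifier per row in the first column, and a rectangular
numeric body.  Gene sets are plain text, one identifier per line, with
``#`` comment lines ignored.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import AlignmentError, ParseError, ValidationError

logger = logging.getLogger(__name__)

MIN_TIMEPOINTS = 4


@dataclass
class ExpressionDataset:
    """A pair of time-aligned expression matrices.

    The *internal* group holds the genes whose dynamics are being
    decomposed (the state of the model); the *external* group holds the
    regulators treated as the control input.  Both matrices share one
    time grid of ``T`` samples; all computation downstream uses the
    sample index ``t = 1..T`` and treats the labels as metadata.
    """

    name: str
    internal_ids: list[str]
    external_ids: list[str]
    internal_matrix: np.ndarray  # N1 x T
    external_matrix: np.ndarray  # N2 x T
    time_labels: list[str] = field(default_factory=list)

    @property
    def n_internal(self) -> int:
        return self.internal_matrix.shape[0]

    @property
    def n_external(self) -> int:
        return self.external_matrix.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.internal_matrix.shape[1]

    def validate(self) -> "ExpressionDataset":
        n1, t1 = self.internal_matrix.shape
        n2, t2 = self.external_matrix.shape
        if t1 != t2:
            raise AlignmentError(
                f"internal matrix has T={t1} but external has T={t2}"
            )
        if t1 < MIN_TIMEPOINTS:
            raise ValidationError(
                f"need at least {MIN_TIMEPOINTS} time points, got {t1}"
            )
        if n1 < 2:
            raise ValidationError(f"internal group needs >= 2 genes, got {n1}")
        if n2 < 1:
            raise ValidationError(f"external group needs >= 1 gene, got {n2}")
        for tag, ids, n in (
            ("internal", self.internal_ids, n1),
            ("external", self.external_ids, n2),
        ):
            if len(ids) != n:
                raise ValidationError(
                    f"{tag} id list length {len(ids)} != matrix rows {n}"
                )
            dupes = _duplicates(ids)
            if dupes:
                raise ValidationError(
                    f"duplicate {tag} gene IDs: {sorted(dupes)}"
                )
        for tag, mat in (
            ("internal", self.internal_matrix),
            ("external", self.external_matrix),
        ):
            if not np.all(np.isfinite(mat)):
                raise ValidationError(
                    f"{tag} matrix contains non-finite values; missing data "
                    "is not supported"
                )
        if self.time_labels and len(self.time_labels) != t1:
            raise ValidationError(
                f"{len(self.time_labels)} time labels for T={t1} samples"
            )
        return self


def _duplicates(ids: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for i in ids:
        if i in seen:
            dupes.add(i)
        seen.add(i)
    return dupes


def read_expression_matrix(
    path: str | Path, delimiter: str = "\t"
) -> tuple[list[str], np.ndarray, list[str]]:
    """Read a delimited expression matrix.

    Returns ``(gene_ids, matrix, time_labels)`` with rows in file order.
    Raises :class:`ParseError` for ragged rows or non-numeric cells
    (naming the offending line / coordinate) and :class:`ValidationError`
    for duplicated gene IDs.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    rows = [ln.split(delimiter) for ln in lines if ln.strip()]
    if len(rows) < 2:
        raise ParseError(f"{path}: need a header row and at least one gene row")
    header = rows[0]
    # a leading corner cell above the ID column is tolerated
    body_width = len(rows[1])
    if len(header) == body_width:
        time_labels = [h.strip() for h in header[1:]]
    elif len(header) == body_width - 1:
        time_labels = [h.strip() for h in header]
    else:
        raise ParseError(
            f"{path}: header has {len(header)} fields but line 2 has "
            f"{body_width}"
        )
    t = len(time_labels)
    ids: list[str] = []
    values = np.empty((len(rows) - 1, t), dtype=float)
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != t + 1:
            raise ParseError(
                f"{path}: line {r} has {len(row)} fields, expected {t + 1}"
            )
        ids.append(row[0].strip())
        for c, cell in enumerate(row[1:]):
            try:
                values[r - 2, c] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} at line {r}, "
                    f"column {c + 2}"
                ) from None
    dupes = _duplicates(ids)
    if dupes:
        raise ValidationError(f"{path}: duplicate gene IDs: {sorted(dupes)}")
    return ids, values, time_labels


def write_expression_matrix(
    path: str | Path,
    ids: Sequence[str],
    matrix: np.ndarray,
    time_labels: Sequence[str] | None = None,
    delimiter: str = "\t",
) -> None:
    """Write a matrix in the format :func:`read_expression_matrix` accepts.

    Values are written with ``repr`` so that a round trip is bitwise exact.
    """
    path = Path(path)
    matrix = np.asarray(matrix, dtype=float)
    if time_labels is None:
        time_labels = [f"t{j + 1}" for j in range(matrix.shape[1])]
    with path.open("w") as fh:
        fh.write("gene_id" + delimiter + delimiter.join(time_labels) + "\n")
        for gid, row in zip(ids, matrix):
            fh.write(
                gid + delimiter
                + delimiter.join(repr(float(v)) for v in row) + "\n"
            )


def read_gene_set(path: str | Path) -> set[str]:
    """Read a gene list: one ID per line, ``#`` comments and blanks skipped."""
    path = Path(path)
    out: set[str] = set()
    for ln in path.read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        out.add(ln)
    if not out:
        raise ValidationError(f"{path}: gene set is empty")
    return out


def assemble_dataset(
    internal: tuple[Sequence[str], np.ndarray],
    external: tuple[Sequence[str], np.ndarray],
    time_labels: Sequence[str] | None = None,
    name: str = "dataset",
    log2: bool = False,
    center: bool = False,
) -> ExpressionDataset:
    """Build and validate an :class:`ExpressionDataset`.

    Genes shared between the internal and external groups are permitted
    (regulators may sit inside the modelled group) but logged.  Expression
    values are used as-is by default; ``log2`` applies ``log2(x + 1)`` and
    ``center`` removes each gene's mean, both off by default so that raw
    abundance units flow through the model unchanged.
    """
    int_ids, int_mat = list(internal[0]), np.asarray(internal[1], dtype=float)
    ext_ids, ext_mat = list(external[0]), np.asarray(external[1], dtype=float)
    if int_mat.shape[1] != ext_mat.shape[1]:
        raise AlignmentError(
            f"internal matrix has T={int_mat.shape[1]} but external has "
            f"T={ext_mat.shape[1]}"
        )
    if log2:
        int_mat = np.log2(int_mat + 1.0)
        ext_mat = np.log2(ext_mat + 1.0)
    if center:
        int_mat = int_mat - int_mat.mean(axis=1, keepdims=True)
        ext_mat = ext_mat - ext_mat.mean(axis=1, keepdims=True)
    ds = ExpressionDataset(
        name=name,
        internal_ids=int_ids,
        external_ids=ext_ids,
        internal_matrix=int_mat,
        external_matrix=ext_mat,
        time_labels=list(time_labels) if time_labels else [],
    ).validate()
    overlap = set(int_ids) & set(ext_ids)
    if overlap:
        logger.warning(
            "%s: %d gene(s) present in both groups: %s",
            name, len(overlap), sorted(overlap),
        )
    for tag, mat, ids in (
        ("internal", int_mat, int_ids),
        ("external", ext_mat, ext_ids),
    ):
        flat = np.where(mat.std(axis=1) == 0)[0]
        if flat.size:
            logger.warning(
                "%s: %d zero-variance %s gene(s) retained: %s",
                name, flat.size, tag, [ids[i] for i in flat[:10]],
            )
    return ds
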