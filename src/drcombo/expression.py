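"""Gene x sample expression matrices: TSV/GCT text I/O, replicate averaging, log2 ratios.

All downstream stages consume :class:`ExpressionMatrix`, a thin ordered
container over a dense float matrix. The scale of the values is always
explicit (``scale_tag``): the log2-ratio constructor refuses to guess whether
an input file is linear or log2 — silent scale guessing is the classic source
of wrong signatures.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SCALE_TAGS = frozenset(
    {"log2_expression", "linear_expression", "log2_ratio", "landmark_response"}
)

_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


class ParseError(ValueError):
    """Malformed expression file; message names the offending line."""


@dataclass
class ProfileMetadata:
    """Provenance of one perturbation profile (a TF or a molecule)."""

    perturbagen_id: str
    perturbagen_kind: str = "none"
    inchikey: str | None = None
    replicate_group: str | None = None

    def __post_init__(self) -> None:
        if not self.perturbagen_id:
            raise ValueError("perturbagen_id must be non-empty")
        if self.perturbagen_kind not in {"tf_overexpression", "small_molecule", "none"}:
            raise ValueError(f"unknown perturbagen_kind {self.perturbagen_kind!r}")
        if self.inchikey is not None and not _INCHIKEY_RE.match(self.inchikey):
            raise ValueError(f"malformed InChIKey {self.inchikey!r} (expected 14-10-1 blocks)")


@dataclass
class ExpressionMatrix:
    """Dense gene x sample matrix with ordered identifiers and an explicit scale.

    Parameters
    ----------
    gene_ids
        Row identifiers, in file/row order. Duplicates are permitted only
        transiently (before :func:`aggregate_duplicates`).
    sample_ids
        Unique column identifiers.
    values
        ``(len(gene_ids), len(sample_ids))`` float array; NaN marks an
        explicitly missing value, anything else must be finite.
    scale_tag
        One of ``log2_expression``, ``linear_expression``, ``log2_ratio``,
        ``landmark_response``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale_tag: str = "log2_expression"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        bad = ~(np.isfinite(self.values) | np.isnan(self.values))
        if bad.any():
            raise ValueError("values must be finite or NaN (explicitly missing)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def has_duplicate_genes(self) -> bool:
        return len(set(self.gene_ids)) != len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.gene_ids),
            list(self.sample_ids),
            self.values.copy(),
            self.scale_tag,
            dict(self.metadata),
        )


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in {"tsv", "gct"}:
            raise ValueError(f"unknown format {format!r}")
        return format
    return "gct" if path.suffix.lower() == ".gct" else "tsv"


def _parse_body(
    lines: list[str], header_lineno: int, path: Path
) -> tuple[list[str], list[str], np.ndarray]:
    header = lines[0].rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ParseError(
            f"{path}:{header_lineno}: duplicate sample id(s) {dupes} in header"
        )
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for offset, raw in enumerate(lines[1:], start=header_lineno + 1):
        if not raw.strip():
            continue
        cells = raw.rstrip("\n").split("\t")
        if len(cells) != len(sample_ids) + 1:
            raise ParseError(
                f"{path}:{offset}: expected {len(sample_ids) + 1} columns, got {len(cells)}"
            )
        gene_ids.append(cells[0])
        row = []
        for col, cell in zip(sample_ids, cells[1:]):
            if cell in ("", "NA", "NaN", "nan"):
                row.append(np.nan)
                continue
            try:
                row.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path}:{offset}: non-numeric cell {cell!r} in column {col!r}"
                ) from None
        rows.append(row)
    values = np.asarray(rows, dtype=float) if rows else np.empty((0, len(sample_ids)))
    return gene_ids, sample_ids, values


def read_matrix(
    path: str | Path,
    format: str | None = None,
    scale_tag: str = "log2_expression",
    aggregate: bool = False,
) -> ExpressionMatrix:
    """Read a TSV or GCT 1.2 text expression matrix.

    TSV layout: header row of sample ids, first column gene ids. GCT 1.2
    layout: ``#1.2`` line, ``<n_genes>\\t<n_samples>`` dims line, then the
    same body. Row order is preserved. Duplicate gene rows raise unless
    ``aggregate=True``, in which case they are mean-collapsed.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    lines = path.read_text().splitlines(keepends=True)
    if fmt == "gct":
        if not lines or not lines[0].startswith("#1.2"):
            raise ParseError(f"{path}:1: expected GCT version line '#1.2'")
        if len(lines) < 3:
            raise ParseError(f"{path}:2: truncated GCT file")
        dims = lines[1].split()
        if len(dims) != 2 or not all(d.isdigit() for d in dims):
            raise ParseError(f"{path}:2: malformed dims line {lines[1].strip()!r}")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        gene_ids, sample_ids, values = _parse_body(lines[2:], 3, path)
        if len(gene_ids) != n_genes or len(sample_ids) != n_samples:
            raise ParseError(
                f"{path}:2: dims line says {n_genes}x{n_samples} but body has "
                f"{len(gene_ids)}x{len(sample_ids)}"
            )
    else:
        if not lines:
            raise ParseError(f"{path}:1: empty file")
        gene_ids, sample_ids, values = _parse_body(lines, 1, path)
    m = ExpressionMatrix(gene_ids, sample_ids, values, scale_tag)
    if m.has_duplicate_genes():
        if not aggregate:
            raise ParseError(
                f"{path}: duplicate gene row ids; pass aggregate=True to mean-collapse"
            )
        m = aggregate_duplicates(m)
    return m


def write_matrix(m: ExpressionMatrix, path: str | Path, format: str | None = None) -> Path:
    """Write TSV or GCT text plus a sidecar ``<path>.meta.json`` with scale and provenance."""
    path = Path(path)
    fmt = _infer_format(path, format)
    df = m.to_frame()
    with open(path, "w") as fh:
        if fmt == "gct":
            fh.write("#1.2\n")
            fh.write(f"{m.shape[0]}\t{m.shape[1]}\n")
        fh.write("gene_id\t" + "\t".join(m.sample_ids) + "\n")
        for gid, row in zip(m.gene_ids, df.to_numpy()):
            fh.write(gid + "\t" + "\t".join(format_float(v) for v in row) + "\n")
    sidecar = path.with_name(path.name + ".meta.json")
    sidecar.write_text(
        json.dumps(
            {"scale_tag": m.scale_tag, "format": fmt, "provenance": m.metadata},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return path


def format_float(v: float) -> str:
    if np.isnan(v):
        return "NA"
    return repr(float(v))


def aggregate_duplicates(m: ExpressionMatrix, how: str = "mean") -> ExpressionMatrix:
    """Mean-collapse duplicate gene rows; first-occurrence order is kept.

    Idempotent: a matrix without duplicate ids is returned unchanged.
    """
    if how != "mean":
        raise ValueError(f"unsupported aggregation {how!r}")
    if not m.has_duplicate_genes():
        return m
    df = m.to_frame()
    order = list(dict.fromkeys(m.gene_ids))
    agg = df.groupby(level=0, sort=False).mean().loc[order]
    out = ExpressionMatrix(order, m.sample_ids, agg.to_numpy(), m.scale_tag, dict(m.metadata))
    out.metadata["aggregated"] = "mean"
    return out


def average_columns(
    m: ExpressionMatrix, groups: Mapping[str, str]
) -> ExpressionMatrix:
    """Average replicate columns into one column per group.

    ``groups`` maps every sample id to a group name; group column order is
    first appearance of each group among ``m.sample_ids``.
    """
    missing = [s for s in m.sample_ids if s not in groups]
    if missing:
        raise ValueError(f"samples not assigned to any group: {missing}")
    group_order = list(dict.fromkeys(groups[s] for s in m.sample_ids))
    cols = []
    for g in group_order:
        idx = [j for j, s in enumerate(m.sample_ids) if groups[s] == g]
        if not idx:
            raise ValueError(f"empty group {g!r}")
        cols.append(m.values[:, idx].mean(axis=1))
    return ExpressionMatrix(
        list(m.gene_ids), group_order, np.column_stack(cols), m.scale_tag, dict(m.metadata)
    )


def _to_log2(m: ExpressionMatrix) -> np.ndarray:
    if m.scale_tag == "linear_expression":
        if np.nanmin(m.values) <= 0:
            raise ValueError("non-positive value in linear-scale matrix; cannot log2")
        return np.log2(m.values)
    return m.values


def log2_ratio(
    target: ExpressionMatrix, source: ExpressionMatrix, paired: bool = False
) -> ExpressionMatrix:
    """Target-over-source log2 ratio profile.

    paired=True pairs replicate columns by order and returns a
    replicate-resolved ratio matrix (one column per pair), the form the
    signature stage consumes. paired=False collapses each side to its
    linear-space mean first and returns a single consensus column.
    """
    if target.gene_ids != source.gene_ids:
        raise ValueError("target and source gene ids differ (order-sensitive)")
    t, s = _to_log2(target), _to_log2(source)
    if paired:
        if t.shape[1] != s.shape[1]:
            raise ValueError(
                f"paired mode needs equal column counts, got {t.shape[1]} vs {s.shape[1]}"
            )
        vals = t - s
        cols = [f"ratio_{j + 1}" for j in range(t.shape[1])]
    else:
        vals = (np.log2(np.mean(2.0**t, axis=1)) - np.log2(np.mean(2.0**s, axis=1)))[:, None]
        cols = ["log2_ratio"]
    out = ExpressionMatrix(list(target.gene_ids), cols, vals, "log2_ratio")
    out.metadata = {
        "operation": "log2_ratio",
        "paired": paired,
        "pairing_rule": "by column order" if paired else None,
    }
    return out
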