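"""Direct-reprogramming characteristic signatures from TF-response / target-ratio concordance.

A gene belongs to the DR-characteristic signature when its response to
overexpression of the reprogramming TFs moves concordantly with its
source-to-target expression change. Concordance is scored per gene as the
Pearson correlation across paired (TF response, target replicate-ratio)
observations; a sweep of correlation thresholds yields nested signatures of
decreasing size.

Per-gene correlation needs several paired observations per gene: the panel
columns (one per TF-overexpression profile) are paired by index with the
replicate-resolved target/source log-ratio columns. With few pairs the null
correlation is heavy-tailed (for 3 points, |r| >= 0.9 occurs for ~14% of
unrelated genes), so thresholding is only informative with >= ~5 pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from drcombo.expression import ExpressionMatrix, format_float
from drcombo.optimize import MoleculeLibrary
from drcombo.orthologs import OrthologMap


class SignatureError(ValueError):
    """Raised when no gene survives a threshold, or panels are incompatible."""


@dataclass
class TFResponsePanel:
    """Per-TF overexpression responses restricted to common orthologs (r x t)."""

    ortholog_ids: list[str]
    tf_names: list[str]
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.shape != (len(self.ortholog_ids), len(self.tf_names)):
            raise ValueError("responses shape must be (r, t)")
        if len(self.tf_names) < 1:
            raise ValueError("panel needs at least one TF column")

    @property
    def t(self) -> int:
        return len(self.tf_names)


@dataclass
class TargetReplicatePanel:
    """Replicate-resolved target/source log2 ratios (r x m) plus their row-mean consensus."""

    ortholog_ids: list[str]
    ratios: np.ndarray
    consensus: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.ratios.ndim != 2 or self.ratios.shape[0] != len(self.ortholog_ids):
            raise ValueError("ratios must be (r, m)")
        if self.ratios.shape[1] < 1:
            raise ValueError("need at least one replicate ratio column")
        if self.consensus is None:
            self.consensus = self.ratios.mean(axis=1)
        else:
            self.consensus = np.asarray(self.consensus, dtype=float)
            if not np.allclose(self.consensus, self.ratios.mean(axis=1)):
                raise ValueError("consensus must equal the row mean of ratios")

    @property
    def m(self) -> int:
        return self.ratios.shape[1]


@dataclass
class DRSignature:
    """Threshold-selected genes with their consensus log2-ratio values.

    ``values`` is the target consensus profile restricted to the selected
    genes — the vector every molecule combination is correlated against.
    """

    threshold: float
    gene_ids: list[str]
    values: np.ndarray
    per_gene_corr: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.per_gene_corr = np.asarray(self.per_gene_corr, dtype=float)
        if len(self.gene_ids) < 1:
            raise ValueError("signature must contain at least one gene")
        if not (0.0 <= self.threshold < 1.0):
            raise ValueError("threshold must lie in [0, 1)")
        if self.values.shape != (len(self.gene_ids),):
            raise ValueError("values length must match gene_ids")
        if self.per_gene_corr.shape != (len(self.gene_ids),):
            raise ValueError("per_gene_corr length must match gene_ids")
        if self.threshold > 0:
            defined = self.per_gene_corr[~np.isnan(self.per_gene_corr)]
            if defined.size != self.per_gene_corr.size or (defined < self.threshold).any():
                raise ValueError("all per_gene_corr must be defined and >= threshold")

    @property
    def s(self) -> int:
        return len(self.gene_ids)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("gene_id\tz_value\tcorr\n")
            for g, z, c in zip(self.gene_ids, self.values, self.per_gene_corr):
                fh.write(f"{g}\t{format_float(z)}\t{format_float(c)}\n")
        header = path.with_name(path.name + ".meta.json")
        header.write_text(
            json.dumps({"threshold": self.threshold, "s": self.s}, sort_keys=True) + "\n"
        )
        return path


def build_tf_profile(panel: TFResponsePanel) -> np.ndarray:
    """Average the per-TF response columns into one TF-induced profile."""
    return panel.responses.mean(axis=1)


def per_gene_concordance(
    panel: TFResponsePanel,
    targets: TargetReplicatePanel,
    pairing: str = "by_index",
    method: str = "pearson",
) -> np.ndarray:
    """Per-gene correlation between TF responses and target replicate ratios.

    Columns are paired by index, so the panel must have as many columns as
    the target panel has replicate-ratio columns. Genes with zero variance on
    either side get NaN (undefined), never a value.
    """
    if pairing != "by_index":
        raise ValueError(f"unknown pairing {pairing!r}")
    if panel.ortholog_ids != targets.ortholog_ids:
        raise SignatureError("panel and target ortholog ids differ")
    if panel.t != targets.m:
        raise SignatureError(
            f"by_index pairing requires t = m, got t={panel.t}, m={targets.m}; "
            "average or subset columns first"
        )
    x = panel.responses
    if method == "spearman":
        from scipy.stats import rankdata

        x = rankdata(x, axis=1)
        z = rankdata(targets.ratios, axis=1)
    elif method == "pearson":
        z = targets.ratios
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    xc = x - x.mean(axis=1, keepdims=True)
    zc = z - z.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (zc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (xc * zc).sum(axis=1) / denom
    corr[denom == 0] = np.nan
    return corr


def select_dr_genes(
    corr: np.ndarray, z_prime: TargetReplicatePanel, threshold: float
) -> DRSignature:
    """Threshold the concordance vector into a DR-characteristic signature.

    threshold = 0 keeps every ortholog (the signature is the full consensus
    profile); threshold > 0 keeps genes with a defined correlation at or
    above it. An empty survivor set raises — at very high thresholds no
    DR-characteristic pattern may be identifiable.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (len(z_prime.ortholog_ids),):
        raise ValueError("corr length must match ortholog count")
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    if threshold == 0.0:
        keep = np.ones(corr.size, dtype=bool)
    else:
        keep = (~np.isnan(corr)) & (corr >= threshold)
    if not keep.any():
        raise SignatureError(f"empty signature at threshold {threshold}")
    gene_ids = [g for g, k in zip(z_prime.ortholog_ids, keep) if k]
    return DRSignature(
        threshold=min(threshold, np.nextafter(1.0, 0.0)) if threshold == 1.0 else threshold,
        gene_ids=gene_ids,
        values=z_prime.consensus[keep],
        per_gene_corr=corr[keep],
    )


def restrict_library(
    lib: ExpressionMatrix,
    sig: DRSignature,
    ortholog_map: OrthologMap | None = None,
    inchikeys: Sequence[str] | None = None,
    known_dr_flags: Sequence[bool] | None = None,
) -> MoleculeLibrary:
    """Cut a genes x molecules perturbation matrix down to the signature genes.

    When the signature lives in another species' namespace, ``ortholog_map``
    (signature species -> library species, one-to-one) translates gene ids.
    Every signature gene must resolve to a library row.
    """
    translate = {}
    if ortholog_map is not None:
        translate = dict(ortholog_map.pairs)
    lib_rows = {g: i for i, g in enumerate(lib.gene_ids)}
    rows, missing = [], []
    for g in sig.gene_ids:
        lg = translate.get(g, g)
        if lg in lib_rows:
            rows.append(lib_rows[lg])
        else:
            missing.append(g)
    if missing:
        raise SignatureError(f"signature genes absent from library: {missing}")
    return MoleculeLibrary(
        molecule_ids=list(lib.sample_ids),
        signatures=lib.values[rows, :],
        gene_ids=list(sig.gene_ids),
        inchikeys=list(inchikeys) if inchikeys is not None else None,
        known_dr_flags=list(known_dr_flags) if known_dr_flags is not None else None,
    )
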