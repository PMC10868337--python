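"""Cross-species ortholog mapping: put two expression matrices in one gene space.

The target-cell profiles (mouse) and the landmark perturbation profiles
(human) live in different gene namespaces; correlating them gene-by-gene
requires a one-to-one ortholog map. Many-to-many orthologs are dropped
entirely rather than averaged — deterministic, and no invented weighting.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from drcombo.expression import ExpressionMatrix


@dataclass
class OrthologMap:
    """Ordered list of (species_A_gene_id, species_B_gene_id) pairs, no exact duplicates."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        deduped = list(dict.fromkeys(tuple(p) for p in self.pairs))
        self.pairs = deduped

    def __len__(self) -> int:
        return len(self.pairs)

    def is_one_to_one(self) -> bool:
        a = Counter(p[0] for p in self.pairs)
        b = Counter(p[1] for p in self.pairs)
        return all(v == 1 for v in a.values()) and all(v == 1 for v in b.values())

    def reversed(self) -> "OrthologMap":
        return OrthologMap([(b, a) for a, b in self.pairs])


@dataclass
class AlignedProfiles:
    """Two matrices restricted to shared ortholog rows; row i of both refers to one pair."""

    ortholog_ids: list[str]  # species-A gene ids of the surviving pairs
    pair_ids_b: list[str]  # species-B counterpart, same order
    matrix_A: np.ndarray
    matrix_B: np.ndarray

    def __post_init__(self) -> None:
        r = len(self.ortholog_ids)
        if r < 1:
            raise ValueError("no common orthologs")
        if self.matrix_A.shape[0] != r or self.matrix_B.shape[0] != r:
            raise ValueError("matrix row counts must equal number of ortholog pairs")

    @property
    def r(self) -> int:
        return len(self.ortholog_ids)


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column TSV (gene_a<TAB>gene_b); '#' comments and an optional
    ``gene_a/gene_b`` header line are skipped."""
    pairs: list[tuple[str, str]] = []
    first_data = True
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cells = line.split("\t")
        if len(cells) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        if first_data and cells[0].lower() in {"gene_a", "a", "source"}:
            first_data = False
            continue
        first_data = False
        pairs.append((cells[0], cells[1]))
    return OrthologMap(pairs)


def filter_one_to_one(map: OrthologMap) -> OrthologMap:
    """Keep only pairs whose A-gene and B-gene each occur exactly once.

    Input-order independent as a set: occurrence counts do not depend on
    order, and surviving pairs keep their input order.
    """
    a_counts = Counter(p[0] for p in map.pairs)
    b_counts = Counter(p[1] for p in map.pairs)
    return OrthologMap(
        [p for p in map.pairs if a_counts[p[0]] == 1 and b_counts[p[1]] == 1]
    )


def align(
    profile_A: ExpressionMatrix, profile_B: ExpressionMatrix, map: OrthologMap
) -> AlignedProfiles:
    """Restrict both matrices to ortholog pairs present in each; order follows the map.

    The map must already be one-to-one (apply :func:`filter_one_to_one` first).
    """
    if not map.is_one_to_one():
        raise ValueError("ortholog map is not one-to-one; run filter_one_to_one first")
    row_a = {g: i for i, g in enumerate(profile_A.gene_ids)}
    row_b = {g: i for i, g in enumerate(profile_B.gene_ids)}
    kept = [(a, b) for a, b in map.pairs if a in row_a and b in row_b]
    if not kept:
        raise ValueError("no common orthologs between the two profiles and the map")
    ia = [row_a[a] for a, _ in kept]
    ib = [row_b[b] for _, b in kept]
    return AlignedProfiles(
        ortholog_ids=[a for a, _ in kept],
        pair_ids_b=[b for _, b in kept],
        matrix_A=profile_A.values[ia, :],
        matrix_B=profile_B.values[ib, :],
    )
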