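"""Assessment of predicted combinations: known-active enrichment and target-protein joins.

A predicted combination of n_pred molecules is scored for over-representation
of the K known DR-inducing molecules among the N-molecule candidate universe:
the one-sided hypergeometric upper tail P(X >= x), computed by direct
summation of the probability mass (no normal or chi-square approximation).
The compound-to-protein join simply tallies, for each protein, how many
selected molecules interact with it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from scipy.stats import hypergeom


@dataclass
class EnrichmentInput:
    """2x2 counts: x known actives among n_pred predicted, K known among N total."""

    N: int
    K: int
    n_pred: int
    x: int

    def __post_init__(self) -> None:
        if not (0 <= self.x <= min(self.K, self.n_pred)):
            raise ValueError("need 0 <= x <= min(K, n_pred)")
        if not (0 <= self.K <= self.N):
            raise ValueError("need 0 <= K <= N")
        if not (0 <= self.n_pred <= self.N):
            raise ValueError("need 0 <= n_pred <= N")


def enrichment_pvalue(inp: EnrichmentInput, tail: str = "greater") -> float:
    """Hypergeometric tail probability of the observed known-active overlap.

    tail="greater" (default, the enrichment direction): P(X >= x) summed
    term-by-term over the pmf. tail="two_sided" sums every outcome whose pmf
    does not exceed the observed one (the small-sample exact convention).
    """
    lo = max(0, inp.n_pred - (inp.N - inp.K))
    hi = min(inp.K, inp.n_pred)
    support = range(lo, hi + 1)
    pmf = {k: float(hypergeom.pmf(k, inp.N, inp.K, inp.n_pred)) for k in support}
    if tail == "greater":
        p = sum(pmf[k] for k in support if k >= inp.x)
    elif tail == "two_sided":
        p_obs = pmf.get(inp.x, 0.0)
        p = sum(v for v in pmf.values() if v <= p_obs * (1 + 1e-7))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return min(max(p, 0.0), 1.0)


@dataclass
class InteractionTable:
    """Deduplicated molecule-protein interaction edges."""

    edges: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen = set()
        for e in self.edges:
            e = tuple(e)
            if e in seen:
                raise ValueError(f"duplicate interaction edge {e}")
            seen.add(e)
        self.edges = [tuple(e) for e in self.edges]

    @property
    def protein_degrees(self) -> Counter:
        return Counter(p for _, p in self.edges)


def read_interactions(path: str | Path) -> InteractionTable:
    """Read a molecule_id<TAB>protein_id TSV ('#' comments, optional header)."""
    edges: list[tuple[str, str]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cells = line.split("\t")
        if len(cells) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        if lineno == 1 and cells[0].lower() in {"molecule_id", "molecule", "compound"}:
            continue
        edges.append((cells[0], cells[1]))
    return InteractionTable(edges)


def target_proteins(
    molecule_ids: list[str], table: InteractionTable
) -> list[tuple[str, int]]:
    """Proteins touched by the selection, with the count of selected molecules
    hitting each; sorted by count descending, then protein id."""
    selected = set(molecule_ids)
    counts = Counter(p for m, p in table.edges if m in selected)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
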