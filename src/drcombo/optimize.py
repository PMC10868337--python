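"""Simulated-annealing search for the molecule combination mimicking a DR signature.

The combinatorial problem: over nonempty index sets I of library molecules,

    maximize  f(I) = f_corr(I) + f_mole(I)

where f_corr is the Pearson correlation between the columnwise *sum* of the
selected molecules' signatures and the DR signature, and f_mole penalizes
combinations larger than T molecules: f_mole = 1 for |I| <= T, otherwise
exp(-(|I|/t)^2) with t the number of reprogramming TFs. f_corr <= 1 by
Cauchy-Schwarz and f_mole <= 1, so f <= 2, attained exactly by a selection
whose summed signature is a positive-affine image of the DR signature.

The annealer proposes single-molecule add/remove moves; a worse proposal
with gap d is accepted with probability exp(-d * iteration / n), i.e. an
effective temperature n/iteration that cools as the run proceeds. The
highest f visited (the prediction score) and its selection are tracked
throughout. (A transcription of this rule with the gap written f* - f would
exceed 1 exactly when invoked; the implemented gap is f - f* >= 0, the only
reading that yields a valid probability and standard annealing behaviour.)

For small libraries (n <= 20) an exhaustive enumeration over all 2^n - 1
nonempty subsets serves as an independent optimum oracle.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class DegenerateSelectionError(ValueError):
    """Summed signature has zero variance; correlation undefined for this selection."""


@dataclass
class MoleculeLibrary:
    """Molecule-induced signatures restricted to the DR-characteristic genes (s x n)."""

    molecule_ids: list[str]
    signatures: np.ndarray
    gene_ids: list[str] | None = None
    inchikeys: list[str] | None = None
    known_dr_flags: list[bool] | None = None

    def __post_init__(self) -> None:
        self.signatures = np.asarray(self.signatures, dtype=float)
        n = len(self.molecule_ids)
        if len(set(self.molecule_ids)) != n:
            raise ValueError("molecule ids must be unique")
        if self.signatures.ndim != 2 or self.signatures.shape[1] != n:
            raise ValueError("signatures must be (s, n)")
        if self.gene_ids is not None and len(self.gene_ids) != self.signatures.shape[0]:
            raise ValueError("gene_ids length must equal signature rows")
        for attr in ("inchikeys", "known_dr_flags"):
            v = getattr(self, attr)
            if v is not None and len(v) != n:
                raise ValueError(f"{attr} length must equal number of molecules")

    @property
    def n(self) -> int:
        return len(self.molecule_ids)

    @property
    def s(self) -> int:
        return self.signatures.shape[0]


@dataclass(frozen=True)
class Selection:
    """A nonempty molecule subset as an index set over {0..n-1}."""

    index_set: frozenset[int]
    n: int

    def __post_init__(self) -> None:
        if not self.index_set:
            raise ValueError("empty selections are unrepresentable")
        if min(self.index_set) < 0 or max(self.index_set) >= self.n:
            raise ValueError("index out of range")

    @property
    def k(self) -> int:
        return len(self.index_set)

    @property
    def binary_vector(self) -> np.ndarray:
        c = np.zeros(self.n, dtype=np.int8)
        c[list(self.index_set)] = 1
        return c

    def sorted_indices(self) -> list[int]:
        return sorted(self.index_set)


@dataclass
class ObjectiveConfig:
    """T: max preferred combination size; t: number of DR-inducing TFs; n: library size."""

    n: int
    T: int = 10
    t: int = 3
    mole_exponent: str = "squared_ratio"  # or "ratio_over_t_squared"

    def __post_init__(self) -> None:
        if not (1 <= self.T <= self.n):
            raise ValueError("need 1 <= T <= n")
        if self.t < 1:
            raise ValueError("t must be >= 1")
        if self.mole_exponent not in {"squared_ratio", "ratio_over_t_squared"}:
            raise ValueError(f"unknown mole_exponent {self.mole_exponent!r}")


@dataclass
class AnnealConfig:
    seed: int = 0
    max_iterations: int = 1_000_000
    wall_time_budget: float | None = None
    restarts: int = 1
    initial_k: int | None = None
    trace_stride: int = 1

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.trace_stride < 1:
            raise ValueError("trace_stride must be >= 1")


@dataclass
class AnnealResult:
    """Best-so-far selection and score of an annealing run (all restarts pooled)."""

    best_selection: Selection
    prediction_score: float
    trace: np.ndarray  # (n_recorded, 3): iteration, current f, best f
    accepted_moves: int
    restart_scores: list[float] = field(default_factory=list)
    best_restart: int = 0

    def best_molecule_ids(self, lib: MoleculeLibrary) -> list[str]:
        return [lib.molecule_ids[i] for i in self.best_selection.sorted_indices()]


def f_mole(sel: Selection | int, cfg: ObjectiveConfig) -> float:
    """Cardinality subobjective: 1 for k <= T, else exp(-(k/t)^2), decaying in k."""
    k = sel if isinstance(sel, int) else sel.k
    if k <= cfg.T:
        return 1.0
    if cfg.mole_exponent == "squared_ratio":
        return math.exp(-((k / cfg.t) ** 2))
    return math.exp(-k / cfg.t**2)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    den = math.sqrt(float(ac @ ac) * float(bc @ bc))
    if den == 0.0:
        raise DegenerateSelectionError("zero variance in correlation input")
    return float(ac @ bc) / den


def f_corr(sel: Selection, lib: MoleculeLibrary, sig) -> float:
    """Pearson correlation between the summed selected signatures and the DR signature."""
    ybar = lib.signatures[:, sel.sorted_indices()].sum(axis=1)
    return _pearson(ybar, np.asarray(sig.values, dtype=float))


def objective(sel: Selection, lib: MoleculeLibrary, sig, cfg: ObjectiveConfig) -> float:
    """f = f_corr + f_mole; at most 2 for every selection."""
    return f_corr(sel, lib, sig) + f_mole(sel, cfg)


def propose_neighbor(sel: Selection, rng: np.random.Generator) -> Selection:
    """Flip one molecule: add (p=1/2) a uniform unselected or remove a uniform selected.

    An impossible draw (add at k = n, remove at k = 1) falls through to the
    other move, so the output always differs in exactly one position.
    """
    if sel.n < 2:
        raise ValueError("library of size 1 has no neighborhood")
    add = rng.random() < 0.5
    if add and sel.k == sel.n:
        add = False
    elif not add and sel.k == 1:
        add = True
    if add:
        pool = sorted(set(range(sel.n)) - sel.index_set)
        pick = pool[int(rng.integers(len(pool)))]
        return Selection(sel.index_set | {pick}, sel.n)
    pool = sel.sorted_indices()
    pick = pool[int(rng.integers(len(pool)))]
    return Selection(sel.index_set - {pick}, sel.n)


def accept_probability(
    f_current: float, f_proposed: float, iteration: int, n: int
) -> float:
    """1 for strict improvements; otherwise exp(-(f_current - f_proposed) * iteration / n)."""
    if iteration < 1 or n < 1:
        raise ValueError("iteration and n must be >= 1")
    if f_proposed > f_current:
        return 1.0
    return math.exp(-(f_current - f_proposed) * iteration / n)


def _anneal_once(
    Y: np.ndarray,
    z: np.ndarray,
    obj_cfg: ObjectiveConfig,
    seed_seq: np.random.SeedSequence,
    max_iterations: int,
    wall_deadline: float | None,
    initial_k: int | None,
    trace_stride: int,
) -> tuple[frozenset[int], float, np.ndarray, int]:
    """One restart of the annealing loop.

    State is kept incrementally: a permutation array whose first k entries
    are the selected molecules, the running summed signature ybar and its
    moments, so each proposal costs O(s).
    """
    rng = np.random.Generator(np.random.PCG64(seed_seq))
    s, n = Y.shape
    YT = np.ascontiguousarray(Y.T)  # rows = molecule signatures
    colsum = YT.sum(axis=1)
    colsq = np.einsum("ij,ij->i", YT, YT)
    zc = z - z.mean()
    z_norm = math.sqrt(float(zc @ zc))
    if z_norm == 0.0:
        raise DegenerateSelectionError("DR signature has zero variance")
    zdots = YT @ zc
    fm_table = np.array([0.0] + [f_mole(k, obj_cfg) for k in range(1, n + 1)])

    def corr_from(S1: float, Szy: float, Syy: float) -> float:
        var = Syy - S1 * S1 / s
        if var <= 1e-300:
            return math.nan
        return Szy / (math.sqrt(var) * z_norm)

    # draw a nondegenerate initial state (bounded retries)
    for _ in range(100):
        k = initial_k if initial_k is not None else int(rng.integers(1, min(obj_cfg.T, n) + 1))
        if not (1 <= k <= n):
            raise ValueError("initial_k out of range")
        pos = rng.permutation(n)
        sel = pos[:k]
        ybar = YT[sel].sum(axis=0)
        S1 = float(ybar.sum())
        Szy = float(zc @ ybar)
        Syy = float(ybar @ ybar)
        fc = corr_from(S1, Szy, Syy)
        if not math.isnan(fc):
            break
    else:
        raise DegenerateSelectionError(
            "could not draw a nondegenerate initial selection in 100 attempts"
        )
    loc = np.empty(n, dtype=np.intp)
    loc[pos] = np.arange(n)
    f_cur = fc + fm_table[k]
    best_f = f_cur
    best_set = frozenset(int(i) for i in pos[:k])

    n_rec = (max_iterations + trace_stride - 1) // trace_stride
    trace = np.empty((n_rec + 1, 3))
    trace[0] = (0.0, f_cur, best_f)
    rec = 1
    accepted = 0
    exp_ = math.exp
    CHUNK = 4096
    it = 0
    while it < max_iterations:
        block = min(CHUNK, max_iterations - it)
        u = rng.random((block, 3))
        for b in range(block):
            it += 1
            add = u[b, 0] < 0.5
            if add and k == n:
                add = False
            elif not add and k == 1:
                add = True
            if add:
                j = k + int(u[b, 1] * (n - k))
                i = pos[j]
                col = YT[i]
                d = float(ybar @ col)
                S1n = S1 + colsum[i]
                Szyn = Szy + zdots[i]
                Syyn = Syy + 2.0 * d + colsq[i]
                kn = k + 1
            else:
                j = int(u[b, 1] * k)
                i = pos[j]
                col = YT[i]
                d = float(ybar @ col)
                S1n = S1 - colsum[i]
                Szyn = Szy - zdots[i]
                Syyn = Syy - 2.0 * d + colsq[i]
                kn = k - 1
            fc = corr_from(S1n, Szyn, Syyn)
            if math.isnan(fc):
                f_new = None  # degenerate proposal: rejected as a move
            else:
                f_new = fc + fm_table[kn]
            if f_new is not None and (
                f_new > f_cur or u[b, 2] < exp_(-(f_cur - f_new) * it / n)
            ):
                accepted += 1
                if add:
                    other = pos[k]
                    pos[k], pos[j] = i, other
                    loc[i], loc[other] = k, j
                    ybar = ybar + col
                else:
                    other = pos[k - 1]
                    pos[k - 1], pos[j] = i, other
                    loc[i], loc[other] = k - 1, j
                    ybar = ybar - col
                k = kn
                S1, Szy, Syy = S1n, Szyn, Syyn
                f_cur = f_new
                if f_cur > best_f:
                    best_f = f_cur
                    best_set = frozenset(int(x) for x in pos[:k])
            if it % trace_stride == 0:
                trace[rec] = (it, f_cur, best_f)
                rec += 1
        # periodic refresh kills float drift in the running moments
        ybar = YT[pos[:k]].sum(axis=0)
        S1 = float(ybar.sum())
        Szy = float(zc @ ybar)
        Syy = float(ybar @ ybar)
        fc = corr_from(S1, Szy, Syy)
        if not math.isnan(fc):
            f_cur = fc + fm_table[k]
        if wall_deadline is not None and time.monotonic() > wall_deadline:
            break
    return best_set, best_f, trace[:rec], accepted


def anneal(
    lib: MoleculeLibrary, sig, obj_cfg: ObjectiveConfig, anneal_cfg: AnnealConfig
) -> AnnealResult:
    """Run the annealing search, optionally with independent restarts.

    Fully reproducible: all randomness flows from ``anneal_cfg.seed`` through
    per-restart spawned streams. With restarts the best restart (ties broken
    by restart order) supplies the result; its trace is returned.
    """
    if lib.n < 2:
        raise ValueError("library must contain at least 2 molecules")
    if obj_cfg.n != lib.n:
        raise ValueError("ObjectiveConfig.n must equal the library size")
    z = np.asarray(sig.values, dtype=float)
    if z.shape[0] != lib.s:
        raise ValueError("signature length must match library gene rows")
    deadline = (
        time.monotonic() + anneal_cfg.wall_time_budget
        if anneal_cfg.wall_time_budget is not None
        else None
    )
    seqs = np.random.SeedSequence(anneal_cfg.seed).spawn(anneal_cfg.restarts)
    best: tuple[float, int, frozenset[int], np.ndarray, int] | None = None
    restart_scores: list[float] = []
    for r, sq in enumerate(seqs):
        bset, bf, trace, acc = _anneal_once(
            lib.signatures,
            z,
            obj_cfg,
            sq,
            anneal_cfg.max_iterations,
            deadline,
            anneal_cfg.initial_k,
            anneal_cfg.trace_stride,
        )
        restart_scores.append(bf)
        if best is None or bf > best[0]:
            best = (bf, r, bset, trace, acc)
    assert best is not None
    bf, r, bset, trace, acc = best
    return AnnealResult(
        best_selection=Selection(bset, lib.n),
        prediction_score=float(bf),
        trace=trace,
        accepted_moves=acc,
        restart_scores=[float(x) for x in restart_scores],
        best_restart=r,
    )


def exhaustive_oracle(
    lib: MoleculeLibrary, sig, obj_cfg: ObjectiveConfig, max_n: int = 20
) -> tuple[Selection, float]:
    """Enumerate every nonempty subset (n <= max_n) and return the argmax of f.

    Ties break deterministically toward the smallest subset bitmask (bit i =
    molecule i), i.e. lexicographic on the index set. Degenerate subsets
    (zero-variance sum) are skipped.
    """
    n = lib.n
    if n > max_n:
        raise ValueError(f"refusing exhaustive enumeration for n={n} > max_n={max_n}")
    z = np.asarray(sig.values, dtype=float)
    zc = z - z.mean()
    z_norm = math.sqrt(float(zc @ zc))
    if z_norm == 0.0:
        raise DegenerateSelectionError("DR signature has zero variance")
    Y = lib.signatures
    s = lib.s
    fm_table = np.array([0.0] + [f_mole(k, obj_cfg) for k in range(1, n + 1)])

    def chunk_scores(chunk: np.ndarray) -> np.ndarray:
        bits = ((chunk[:, None] >> np.arange(n)) & 1).astype(float)  # (c, n)
        sums = bits @ Y.T  # (c, s)
        k = bits.sum(axis=1).astype(int)
        S1 = sums.sum(axis=1)
        var = np.einsum("ij,ij->i", sums, sums) - S1**2 / s
        with np.errstate(invalid="ignore", divide="ignore"):
            fc = (sums @ zc) / (np.sqrt(var) * z_norm)
        return np.where(var > 1e-300, fc + fm_table[k], -np.inf)

    masks = np.arange(1, 2**n, dtype=np.int64)
    best_f = -math.inf
    for start in range(0, masks.size, 65536):
        best_f = max(best_f, float(chunk_scores(masks[start : start + 65536]).max()))
    if not math.isfinite(best_f):
        raise DegenerateSelectionError("every subset is degenerate")
    # float noise can split mathematically tied subsets; take the smallest
    # bitmask (lexicographic on index sets) among near-ties
    best_mask = -1
    for start in range(0, masks.size, 65536):
        chunk = masks[start : start + 65536]
        hit = np.nonzero(chunk_scores(chunk) >= best_f - 1e-12)[0]
        if hit.size:
            best_mask = int(chunk[hit[0]])
            break
    idx = frozenset(i for i in range(n) if best_mask >> i & 1)
    return Selection(idx, n), best_f
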