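"""Synthetic study generator: planted DR genes and a planted molecule combination.

Emulates the data shapes the pipeline consumes without any download: mouse
source/target replicate expression, a human TF-overexpression response panel
over landmark genes, a human molecule perturbation library, an ortholog map
between the two namespaces, and known-active labels.

Planted structure
-----------------
* A per-gene true conversion effect z (log2 target/source ratio) drives the
  target matrices.
* For a planted fraction of ortholog genes, each TF-response column equals
  ``response_scale`` times the corresponding replicate log-ratio column plus
  Gaussian noise, so per-gene concordance is high exactly there; every other
  gene's responses are independent noise.
* A planted combination of molecules is built so the *sum* of its member
  signatures is an affine image of z on the planted genes plus Gaussian
  noise: each member carries the masked z plus a centered within-combination
  deviation (the deviations cancel exactly in the sum), so no proper subset
  matches as well as the whole combination. The remaining molecules are
  strong but uncorrelated responders (Gaussian noise with a larger scale).

Everything is drawn from one seeded generator in a fixed order, so a given
seed reproduces the study byte-for-byte.
"""

from __future__ import annotations

import json
import string
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from drcombo.expression import ExpressionMatrix, write_matrix
from drcombo.orthologs import OrthologMap

_ALPHA = np.array(list(string.ascii_uppercase))


@dataclass
class SimConfig:
    """Study-shape and noise parameters of the generator.

    Defaults mirror the real study's scale: 978 landmark genes, 594 common
    orthologs, 3 reprogramming TFs (each with 2 assay replicate profiles,
    giving 6 paired observations per gene — enough for a 0.9 correlation
    threshold to separate signal from the heavy-tailed few-point null), a
    1522-molecule candidate library with 36 known actives.
    """

    p_genes: int = 978
    r_orthologs: int = 594
    t_tfs: int = 3
    profiles_per_tf: int = 2
    m_replicates: int | None = None  # defaults to t_tfs * profiles_per_tf
    n_molecules: int = 1522
    planted_gene_fraction: float = 0.2
    planted_combo_size: int = 5
    noise_sd: float = 0.1
    response_scale: float = 1.0
    seed: int = 0
    # secondary knobs
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    replicate_sd: float = 0.3
    z_sd: float = 1.0
    within_combo_sd: float = 1.0
    library_scale: float = 2.0
    null_response_sd: float = 1.0
    known_total: int = 36
    decoy_pairs: int = 6

    def __post_init__(self) -> None:
        if self.m_replicates is None:
            self.m_replicates = self.t_tfs * self.profiles_per_tf
        if self.m_replicates != self.t_tfs * self.profiles_per_tf:
            raise ValueError(
                "m_replicates must equal t_tfs * profiles_per_tf for by_index pairing"
            )
        if not (0 < self.planted_gene_fraction <= 1):
            raise ValueError("planted_gene_fraction must lie in (0, 1]")
        if not (1 <= self.planted_combo_size <= self.n_molecules):
            raise ValueError("planted_combo_size must lie in [1, n_molecules]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.r_orthologs > self.p_genes:
            raise ValueError("r_orthologs cannot exceed p_genes")


@dataclass
class SimBundle:
    """Everything simulate_study produces, plus the planted truth."""

    config: SimConfig
    source: ExpressionMatrix  # mouse, r x m, log2 expression
    target: ExpressionMatrix  # mouse, r x m, log2 expression
    tf_panel: ExpressionMatrix  # human, p x m, landmark responses
    library: ExpressionMatrix  # human, p x n, landmark responses
    ortholog_map: OrthologMap
    inchikeys: list[str]
    planted_gene_ids: list[str]  # mouse namespace
    planted_molecule_ids: list[str]
    known_dr_ids: list[str]
    z_true: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def _inchikey(rng: np.random.Generator) -> str:
    a = "".join(rng.choice(_ALPHA, 14))
    b = "".join(rng.choice(_ALPHA, 10))
    c = str(rng.choice(_ALPHA))
    return f"{a}-{b}-{c}"


def simulate_study(cfg: SimConfig) -> SimBundle:
    """Generate one synthetic study; fully deterministic in ``cfg.seed``."""
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    r, p, m, n = cfg.r_orthologs, cfg.p_genes, cfg.m_replicates, cfg.n_molecules
    mouse_genes = [f"mmu_G{i:04d}" for i in range(r)]
    human_genes = [f"hsa_G{i:04d}" for i in range(p)]

    # conversion effect and replicate-resolved expression
    z = rng.normal(0.0, cfg.z_sd, r)
    base = rng.normal(cfg.baseline_mean, cfg.baseline_sd, r)
    src = base[:, None] + rng.normal(0.0, cfg.replicate_sd, (r, m))
    tgt = base[:, None] + z[:, None] + rng.normal(0.0, cfg.replicate_sd, (r, m))
    Z = tgt - src  # realized replicate log-ratios

    n_planted = max(1, round(cfg.planted_gene_fraction * r))
    planted_rows = np.sort(rng.choice(r, size=n_planted, replace=False))
    planted_mask = np.zeros(r, dtype=bool)
    planted_mask[planted_rows] = True

    # TF panel: concordant with the realized log-ratios on planted genes only
    responses = rng.normal(0.0, cfg.null_response_sd, (p, m))
    responses[planted_rows, :] = cfg.response_scale * Z[planted_rows, :] + rng.normal(
        0.0, cfg.noise_sd, (n_planted, m)
    )
    tf_cols = [
        f"TF{i + 1}_rep{j + 1}"
        for i in range(cfg.t_tfs)
        for j in range(cfg.profiles_per_tf)
    ]

    # molecule library: planted combination sums to an affine image of masked z
    c = cfg.planted_combo_size
    planted_mols = np.sort(rng.choice(n, size=c, replace=False))
    lib = rng.normal(0.0, cfg.library_scale, (p, n))
    masked_z = np.zeros(p)
    masked_z[planted_rows] = z[planted_rows]  # human row i <-> mouse gene i for i < r
    within = rng.normal(0.0, cfg.within_combo_sd, (p, c))
    within -= within.mean(axis=1, keepdims=True)  # deviations cancel in the sum
    lib[:, planted_mols] = (
        masked_z[:, None] + within + rng.normal(0.0, cfg.noise_sd, (p, c))
    )
    mol_ids = [f"MOL{i + 1:05d}" for i in range(n)]
    inchikeys = [_inchikey(rng) for _ in range(n)]

    # ortholog map: true bijection plus ambiguous decoy pairs to exercise filtering
    pairs = [(mouse_genes[i], human_genes[i]) for i in range(r)]
    for d in range(cfg.decoy_pairs):
        pairs.append((f"mmu_DECOY{d:02d}", f"hsa_DECOYA{d:02d}"))
        pairs.append((f"mmu_DECOY{d:02d}", f"hsa_DECOYB{d:02d}"))

    planted_mol_ids = [mol_ids[i] for i in planted_mols]
    n_decoy_known = max(0, min(cfg.known_total, n) - c)
    non_planted = np.setdiff1d(np.arange(n), planted_mols)
    decoy_known = rng.choice(non_planted, size=min(n_decoy_known, non_planted.size), replace=False)
    known_ids = sorted(planted_mol_ids + [mol_ids[i] for i in decoy_known])

    rep_cols = [f"rep{j + 1}" for j in range(m)]
    return SimBundle(
        config=cfg,
        source=ExpressionMatrix(mouse_genes, rep_cols, src, "log2_expression"),
        target=ExpressionMatrix(mouse_genes, rep_cols, tgt, "log2_expression"),
        tf_panel=ExpressionMatrix(human_genes, tf_cols, responses, "landmark_response"),
        library=ExpressionMatrix(human_genes, mol_ids, lib, "landmark_response"),
        ortholog_map=OrthologMap(pairs),
        inchikeys=inchikeys,
        planted_gene_ids=[mouse_genes[i] for i in planted_rows],
        planted_molecule_ids=planted_mol_ids,
        known_dr_ids=known_ids,
        z_true=z,
    )


def write_bundle(bundle: SimBundle, outdir: str | Path) -> dict:
    """Write every bundle component as text files; returns a path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "source": outdir / "source.tsv",
        "target": outdir / "target.tsv",
        "tf_panel": outdir / "tf_panel.tsv",
        "library": outdir / "library.gct",
        "orthologs": outdir / "orthologs.tsv",
        "known": outdir / "known_dr_molecules.txt",
        "truth": outdir / "truth.json",
    }
    write_matrix(bundle.source, paths["source"])
    write_matrix(bundle.target, paths["target"])
    write_matrix(bundle.tf_panel, paths["tf_panel"])
    write_matrix(bundle.library, paths["library"], format="gct")
    with open(paths["orthologs"], "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in bundle.ortholog_map.pairs:
            fh.write(f"{a}\t{b}\n")
    paths["known"].write_text("\n".join(bundle.known_dr_ids) + "\n")
    truth = {
        "config": asdict(bundle.config),
        "planted_gene_ids": bundle.planted_gene_ids,
        "planted_molecule_ids": bundle.planted_molecule_ids,
        "known_dr_ids": bundle.known_dr_ids,
        "inchikeys": dict(zip(bundle.library.sample_ids, bundle.inchikeys)),
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return {k: str(v) for k, v in paths.items()}


def truth_report(
    bundle: SimBundle,
    selected_gene_ids: list[str] | None = None,
    selected_molecule_ids: list[str] | None = None,
    score: float | None = None,
    oracle_score: float | None = None,
) -> dict:
    """Recovery metrics of pipeline outputs against the planted truth.

    gene sensitivity/specificity for the signature stage, Jaccard overlap for
    the molecule stage, and the prediction-score gap to an oracle optimum
    when one is supplied. All metrics lie in [0, 1] except ``score_gap``.
    """
    report: dict[str, float] = {}
    if selected_gene_ids is not None:
        universe = set(bundle.source.gene_ids)
        sel = set(selected_gene_ids)
        if not sel <= universe:
            raise ValueError(
                "selected gene ids are not in the bundle's target-species namespace"
            )
        planted = set(bundle.planted_gene_ids)
        tp = len(sel & planted)
        fp = len(sel - planted)
        fn = len(planted - sel)
        tn = len(universe) - tp - fp - fn
        report["gene_sensitivity"] = tp / len(planted) if planted else 1.0
        neg = tn + fp
        report["gene_specificity"] = tn / neg if neg else 1.0
    if selected_molecule_ids is not None:
        sel_m = set(selected_molecule_ids)
        if not sel_m <= set(bundle.library.sample_ids):
            raise ValueError("selected molecule ids are not in the bundle's library")
        planted_m = set(bundle.planted_molecule_ids)
        union = sel_m | planted_m
        report["molecule_jaccard"] = len(sel_m & planted_m) / len(union) if union else 1.0
    if score is not None and oracle_score is not None:
        report["score_gap"] = float(oracle_score - score)
    return report
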