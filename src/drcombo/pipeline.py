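"""End-to-end orchestration: ratios -> ortholog alignment -> signatures -> search -> evaluation.

One :func:`run_pipeline` call sweeps the correlation-threshold grid; each
threshold gets an independently seeded annealing run (no warm-starting across
thresholds, so per-threshold results are comparable). All randomness derives
from the single master seed; rerunning an identical config reproduces every
output and the manifest hash.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

import drcombo
from drcombo.evaluate import EnrichmentInput, enrichment_pvalue, read_interactions, target_proteins
from drcombo.expression import read_matrix, log2_ratio
from drcombo.optimize import AnnealConfig, ObjectiveConfig, anneal
from drcombo.orthologs import align, filter_one_to_one, read_ortholog_map
from drcombo.signature import (
    TFResponsePanel,
    TargetReplicatePanel,
    per_gene_concordance,
    restrict_library,
    select_dr_genes,
)

DEFAULT_THRESHOLDS = (0.0, 0.5, 0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class RunConfig:
    source_path: str
    target_path: str
    tf_panel_path: str
    library_path: str
    ortholog_path: str
    outdir: str
    known_path: str | None = None
    interactions_path: str | None = None
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    source_scale: str = "log2_expression"
    response_scale_tag: str = "landmark_response"
    T: int = 10
    t: int = 3
    seed: int = 0
    max_iterations: int = 1_000_000
    restarts: int = 1
    wall_time_budget: float | None = None

    def __post_init__(self) -> None:
        th = tuple(float(x) for x in self.thresholds)
        if any(not (0.0 <= x < 1.0) for x in th):
            raise ValueError("thresholds must each lie in [0, 1)")
        if any(b <= a for a, b in zip(th, th[1:])):
            raise ValueError("thresholds must be strictly increasing")
        self.thresholds = th

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _stage(name: str, path: str | None, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        where = f" (input: {path})" if path else ""
        raise PipelineError(f"stage {name!r} failed{where}: {exc}") from exc


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full threshold sweep; returns (and writes) the output manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log.jsonl"
    log_fh = open(log_path, "w")

    def log(stage: str, **kv) -> None:
        log_fh.write(json.dumps({"stage": stage, **kv}) + "\n")

    t0 = time.monotonic()
    source = _stage("read_source", cfg.source_path, read_matrix, cfg.source_path,
                    scale_tag=cfg.source_scale, aggregate=True)
    target = _stage("read_target", cfg.target_path, read_matrix, cfg.target_path,
                    scale_tag=cfg.source_scale, aggregate=True)
    panel_m = _stage("read_tf_panel", cfg.tf_panel_path, read_matrix, cfg.tf_panel_path,
                     scale_tag=cfg.response_scale_tag, aggregate=True)
    library = _stage("read_library", cfg.library_path, read_matrix, cfg.library_path,
                     scale_tag=cfg.response_scale_tag, aggregate=True)
    omap = _stage("read_orthologs", cfg.ortholog_path, read_ortholog_map, cfg.ortholog_path)
    omap = filter_one_to_one(omap)
    log("inputs", genes_source=source.shape[0], genes_panel=panel_m.shape[0],
        molecules=library.shape[1], ortholog_pairs=len(omap),
        wall_s=round(time.monotonic() - t0, 3))

    ratios = _stage("log2_ratio", cfg.target_path, log2_ratio, target, source, True)
    aligned = _stage("align", cfg.ortholog_path, align, ratios, panel_m, omap)
    targets = TargetReplicatePanel(aligned.ortholog_ids, aligned.matrix_A)
    panel = TFResponsePanel(aligned.ortholog_ids, list(panel_m.sample_ids), aligned.matrix_B)
    corr = _stage("concordance", None, per_gene_concordance, panel, targets)
    log("aligned", r=aligned.r, wall_s=round(time.monotonic() - t0, 3))

    known: set[str] = set()
    if cfg.known_path:
        known = {
            ln.strip() for ln in Path(cfg.known_path).read_text().splitlines() if ln.strip()
        }
    interactions = (
        _stage("read_interactions", cfg.interactions_path, read_interactions,
               cfg.interactions_path)
        if cfg.interactions_path
        else None
    )

    seed_seqs = np.random.SeedSequence(cfg.seed).spawn(len(cfg.thresholds))
    summary_rows = []
    per_threshold = []
    for i, theta in enumerate(cfg.thresholds):
        sig = _stage(f"signature@{theta}", None, select_dr_genes, corr, targets, theta)
        lib = _stage(f"restrict@{theta}", cfg.library_path, restrict_library,
                     library, sig, omap)
        obj_cfg = ObjectiveConfig(n=lib.n, T=cfg.T, t=cfg.t)
        sub_seed = int(seed_seqs[i].generate_state(1)[0] % (2**31))
        a_cfg = AnnealConfig(seed=sub_seed, max_iterations=cfg.max_iterations,
                             restarts=cfg.restarts, wall_time_budget=cfg.wall_time_budget,
                             trace_stride=max(1, cfg.max_iterations // 1000))
        res = _stage(f"anneal@{theta}", None, anneal, lib, sig, obj_cfg, a_cfg)
        best_ids = res.best_molecule_ids(lib)

        report: dict = {
            "threshold": theta,
            "s": sig.s,
            "k_best": res.best_selection.k,
            "prediction_score": res.prediction_score,
            "molecule_ids": best_ids,
            "seed": sub_seed,
            "restart_scores": res.restart_scores,
        }
        if known:
            inp = EnrichmentInput(
                N=lib.n,
                K=len(known & set(lib.molecule_ids)),
                n_pred=len(best_ids),
                x=len(known & set(best_ids)),
            )
            report["enrichment_pvalue"] = enrichment_pvalue(inp)
            report["known_in_best"] = inp.x
        if interactions is not None:
            report["target_proteins"] = target_proteins(best_ids, interactions)

        tdir = outdir / f"threshold_{theta:g}"
        tdir.mkdir(exist_ok=True)
        sig.write(tdir / "signature.tsv")
        (tdir / "result.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        per_threshold.append(report)
        summary_rows.append((theta, sig.s, res.best_selection.k, res.prediction_score,
                             report.get("enrichment_pvalue")))
        log("threshold_done", threshold=theta, s=sig.s, k_best=res.best_selection.k,
            score=res.prediction_score, wall_s=round(time.monotonic() - t0, 3))

    with open(outdir / "summary.tsv", "w") as fh:
        fh.write("threshold\ts\tk_best\tprediction_score\tenrichment_pvalue\n")
        for theta, s, k, score, pval in summary_rows:
            fh.write(f"{theta:g}\t{s}\t{k}\t{float(score)!r}\t"
                     f"{'NA' if pval is None else repr(float(pval))}\n")

    manifest = {
        "package_version": drcombo.__version__,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "r_common_orthologs": aligned.r,
        "thresholds": list(cfg.thresholds),
        "results": per_threshold,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log("done", wall_s=round(time.monotonic() - t0, 3))
    log_fh.close()
    return manifest
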