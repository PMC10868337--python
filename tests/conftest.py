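import numpy as np
import pytest

from drcombo import (
    SimConfig,
    TargetReplicatePanel,
    TFResponsePanel,
    align,
    filter_one_to_one,
    per_gene_concordance,
    simulate_study,
)
from drcombo.expression import log2_ratio


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small zero-noise study: 2-molecule planted combination, all genes planted."""
    cfg = SimConfig(
        p_genes=50,
        r_orthologs=40,
        n_molecules=12,
        planted_combo_size=2,
        planted_gene_fraction=1.0,
        noise_sd=0.0,
        seed=3,
    )
    return simulate_study(cfg)


def stage_signature_inputs(bundle):
    """Run the pre-optimizer stages of the pipeline on a bundle."""
    ratios = log2_ratio(bundle.target, bundle.source, paired=True)
    omap = filter_one_to_one(bundle.ortholog_map)
    aligned = align(ratios, bundle.tf_panel, omap)
    targets = TargetReplicatePanel(aligned.ortholog_ids, aligned.matrix_A)
    panel = TFResponsePanel(
        aligned.ortholog_ids, list(bundle.tf_panel.sample_ids), aligned.matrix_B
    )
    corr = per_gene_concordance(panel, targets)
    return omap, panel, targets, corr


@pytest.fixture(scope="session")
def tiny_staged(tiny_bundle):
    return stage_signature_inputs(tiny_bundle)


def random_instance(seed, s=50, n=12):
    """A random library/signature pair for optimizer tests."""
    from drcombo.optimize import MoleculeLibrary
    from drcombo.signature import DRSignature

    rng = np.random.default_rng(seed)
    Y = rng.normal(size=(s, n))
    z = rng.normal(size=s)
    sig = DRSignature(0.0, [f"g{i}" for i in range(s)], z, np.zeros(s))
    lib = MoleculeLibrary([f"M{i}" for i in range(n)], Y)
    return lib, sig
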