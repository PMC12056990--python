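import numpy as np
import pytest

from pathomics import synthetic


@pytest.fixture
def small_scene():
    """A modest non-overlapping nuclei scene with ground truth."""
    spec = synthetic.NucleiSceneSpec(
        width_px=256, height_px=256, n_nuclei=12, radius_px_mean=8.0,
        radius_px_sd=1.0, overlap_allowed=False, seed=1,
    )
    return synthetic.generate_patch(spec)


@pytest.fixture
def planted_cohort():
    """Feature cohort with 5 informative of 30 features at effect 2."""
    spec = synthetic.CohortSpec(
        n_samples=120, n_features=30, n_informative=5, effect_size=2.0, seed=11,
    )
    return synthetic.generate_cohort(spec)


@pytest.fixture
def expression_setup():
    """60-gene expression matrix with one planted up- and one down-set."""
    gene_sets = synthetic.make_gene_sets(60, 4, 10, seed=0)
    spec = synthetic.ExpressionSpec(
        n_genes=60, n_samples=40, gene_sets=gene_sets,
        planted_up_sets=("SET_00",), planted_down_sets=("SET_01",),
        effect_size=1.5, seed=0,
    )
    groups = np.array(["high"] * 20 + ["low"] * 20)
    expr = synthetic.generate_expression(spec, groups)
    return expr, groups, gene_sets
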