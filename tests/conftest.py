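import numpy as np
import pytest

import mtlassosum as mt
from mtlassosum.ldref import partition_blocks


@pytest.fixture(scope="session")
def small_panel_blocks():
    """600-SNP, 300-subject synthetic panel with 100-SNP LD blocks (maf scaling)."""
    return mt.make_fixture_panel(300, 600, block_size=100, seed=101)


@pytest.fixture(scope="session")
def sd_panel_blocks():
    """Panel standardized by empirical SD, so block LD is exact Pearson correlation."""
    return mt.make_fixture_panel(250, 40, block_size=8, seed=103, scale="sd")


@pytest.fixture(scope="session")
def reference_sim(small_panel_blocks):
    """Effects and summary statistics drawn under the reference scenario."""
    panel, blocks = small_panel_blocks
    p = panel.n_snps
    scenario = mt.SimulationScenario.reference(p_snps=p, n_gwas=(5000, 5000))
    rng = np.random.default_rng(202)
    status = mt.assign_causal_status(p, scenario, rng)
    effects = mt.draw_effects(status, scenario, rng)
    n = np.array([5000, 5000])
    r = mt.draw_region_sumstats(effects.beta, blocks, n, rng)
    ss = mt.wrap_sumstats(r, n, blocks)
    model = mt.constant_model(*scenario.constant_totals, p)
    return {"scenario": scenario, "effects": effects, "ss": ss, "model": model,
            "panel": panel, "blocks": blocks}


@pytest.fixture(scope="session")
def tiny_sd_instance(sd_panel_blocks):
    """A p=8, q=2 convex instance on a single exact-correlation LD block."""
    panel, blocks = sd_panel_blocks
    sub = blocks.subset(np.arange(panel.n_snps) < 8)
    rng = np.random.default_rng(7)
    r = rng.normal(0.0, 0.02, (8, 2))
    n = np.array([800.0, 1200.0])
    model = mt.constant_model((0.4, 0.3), 0.15, 8)
    return {"blocks": sub, "r": r, "n": n, "model": model}
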