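"""Shared fixtures: the expensive simulations are built once per session and
reused by module tests and the acceptance suite."""

import numpy as np
import pytest

import cascade_pbm as c


@pytest.fixture(scope="session")
def cre_recovery():
    """Planted-site tiling experiment: 166-bp region with the ETS-like
    consensus written at offset 40, simulated at the default noise level."""
    planted = c.ets_like_complex()
    seq = c.synthetic_cre(166, rng_seed=3, sites={40: planted.consensus})
    manifest = c.design_cre_array({"cre": seq}, n_background=200, rng_seed=2)
    table = c.simulate_array(manifest, planted, rng_seed=5)
    zres = c.zscore_pipeline(manifest, table)
    motif = c.build_cre_motif(manifest, zres, "cre")
    return {
        "planted": planted,
        "seq": seq,
        "site_offset": 40,
        "manifest": manifest,
        "intensities": table,
        "zres": zres,
        "motif": motif,
    }


@pytest.fixture(scope="session")
def null_screen_results():
    """1,000 null SNP pairs, two technical replicates, screened."""
    manifest, tables = c.make_null_screen(1000, rng_seed=7)
    s1 = c.screen(manifest, tables[0], label="rep1")
    s2 = c.screen(manifest, tables[1], label="rep2")
    calls = c.reproducible_hits(s1, s2, factor="cof")
    return {"manifest": manifest, "tables": tables, "s1": s1, "s2": s2, "calls": calls}


@pytest.fixture(scope="session")
def planted_screen_results():
    """1,000 SNP pairs with 50 planted gain-of-recruitment effects."""
    manifest, tables, gains = c.make_planted_screen(1000, 50, rng_seed=11)
    s1 = c.screen(manifest, tables[0], label="rep1")
    s2 = c.screen(manifest, tables[1], label="rep2")
    calls = c.reproducible_hits(s1, s2, factor="cof")
    return {"manifest": manifest, "gains": gains, "s1": s1, "s2": s2, "calls": calls}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
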