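import numpy as np
import pytest

import hitransmet as ht
from hitransmet import pipeline as pl


@pytest.fixture(scope="session")
def pfm_library():
    return pl.toy_pfm_library()


@pytest.fixture(scope="session")
def cassette_pair(pfm_library):
    """WT + Sc cassettes for the first library motif (seed-fixed)."""
    rng = np.random.default_rng(11)
    return ht.design_cassette_pair(pfm_library[0], pfm_library, rng)


@pytest.fixture(scope="session")
def reference(cassette_pair):
    """Sc-cassette amplicon on a 600 bp backbone (shared across tests)."""
    wt, sc = cassette_pair
    rng = np.random.default_rng(5)
    backbone = ht.build_backbone(
        600, 0.036, rng,
        forbidden=[wt.barcode5, wt.barcode3],
    )
    return ht.make_amplicon(backbone, sc, 150)


@pytest.fixture(scope="session")
def wt_reference(cassette_pair, reference):
    """WT cassette on the same backbone as the Sc reference."""
    wt, sc = cassette_pair
    backbone = (
        reference.sequence[: reference.cassette_offset]
        + reference.sequence[reference.cassette_offset + len(sc.sequence):]
    )
    return ht.make_amplicon(backbone, wt, reference.cassette_offset)


@pytest.fixture(scope="session")
def noise_free_run(cassette_pair):
    """Full pipeline on a noise-free library (conversion 1, no errors/dups)."""
    from hitransmet import simulate as sim

    config = pl.RunConfig(seed=13, n_molecules=40, pcr_dup_mean=0.0, seq_error_rate=0.0)
    wt, sc = cassette_pair
    refs = pl.build_references([wt, sc], config)
    profile = sim.get_preset(
        "ESC_minusSssI", conversion_rate=1.0, noncg_meth_rate=0.0
    )
    return pl.run_condition(refs[sc.label], profile, "Sc", config)
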