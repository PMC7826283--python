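import pytest

from m5ckit import synthetic_data as sim


@pytest.fixture(scope="session")
def small_transcriptome():
    """20 genes, all with a planted 3'UTR motif site, half in hairpins."""
    return sim.make_transcriptome(
        20, motif_fraction=1.0, hairpin_fraction=0.5, seed=11, stoichiometry=0.5
    )


@pytest.fixture(scope="session")
def mixed_transcriptome():
    """30 genes: 80% motif sites, the rest plain-C sites."""
    return sim.make_transcriptome(
        30, motif_fraction=0.8, hairpin_fraction=0.5, seed=7, stoichiometry=(0.1, 0.5, 0.9)
    )
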