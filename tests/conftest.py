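import numpy as np
import pytest

import coldmir as cm


@pytest.fixture(scope="session")
def table25():
    """Bundled zebrafish cold-acclimation differential miRNA table."""
    return cm.zebrafish_cold_mirnas()


@pytest.fixture(scope="session")
def small_cfg():
    """Small but non-trivial simulation configuration."""
    return cm.SimConfig(
        n_mirnas=40,
        n_genes=500,
        depth_nc=100_000,
        depth_wc=200_000,
        frac_de_mirna=0.2,
        targets_per_mirna=15,
        frac_de_gene=0.2,
        utr_len=100,
        seed=42,
    )


def star_network(n_coherent: int, n_incoherent: int) -> cm.RegNetwork:
    """One up-regulated miRNA fanning out to down (coherent) and up genes."""
    genes = {}
    for i in range(n_coherent):
        genes[f"gc{i}"] = "down"
    for i in range(n_incoherent):
        genes[f"gi{i}"] = "up"
    return cm.build_network({"m1": "up"}, genes, [("m1", g) for g in genes])


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
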