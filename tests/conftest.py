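import numpy as np
import pandas as pd
import pytest

from cspic.genodata import GenotypeMatrix


def make_matrix(dosage, ids=None, locus_ids=None, chrom=None, pos=None):
    """Small helper: GenotypeMatrix from a plain array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    ids = ids or [f"I{i}" for i in range(n)]
    locus_ids = locus_ids or [f"L{j}" for j in range(m)]
    loci = pd.DataFrame({"id": locus_ids})
    if chrom is not None:
        loci["chrom"] = chrom
    if pos is not None:
        loci["pos"] = pos
    return GenotypeMatrix(ids, loci, dosage)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """One simulated connected dataset at reduced scale, shared by tests
    that only need plausible structure (not the default study scale)."""
    from cspic.simulate import SimulationConfig, simulate_cspic

    dh_spec = [
        ("POP1", "C783", "C229", 40),
        ("POP2", "C783", "UH306", 40),
        ("POP3", "C783", "EH", 40),
        ("POP4", "C229", "UH306", 40),
        ("POP5", "C783", "C116A", 40),
    ]
    cfg = SimulationConfig(
        seed=99, n_chrom=3, map_length_per_chrom=120.0, n_loci=400,
        dh_pop_spec=dh_spec,
    )
    from cspic.simulate import simulate_cspic

    return simulate_cspic(cfg)
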