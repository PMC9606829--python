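import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import sploshkit as sk

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_map() -> sk.GeneticMap:
    return sk.GeneticMap.default()


@pytest.fixture(scope="session")
def small_map() -> sk.GeneticMap:
    """One chromosome, SNPs at 0, 10, 20, 30, 40 cM."""
    return sk.GeneticMap(pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(5)],
        "chrom": "chr01",
        "pos_cM": [0.0, 10.0, 20.0, 30.0, 40.0]}))


def make_panel(gmap, calls, groups=None, species=None):
    calls = np.asarray(calls, dtype=np.int8)
    n = calls.shape[0]
    ids = [f"ind{i}" for i in range(n)]
    meta = sk.make_metadata(
        ids,
        species if species is not None else ["sp"] * n,
        groups if groups is not None else ["unknown"] * n)
    return sk.GenotypePanel(gmap, meta, calls)


@pytest.fixture(scope="session")
def trio_panel(default_map):
    """Zero-noise father x mother -> child plus unrelated individuals."""
    model = sk.SpeciesModel(n_species=2, fst=0.3)
    groups = [sk.FounderGroup("domestica", 4, "cultivar"),
              sk.FounderGroup("sieversii", 4, "wild")]
    rng = np.random.default_rng(11)
    panel, truth = sk.simulate_founders(model, groups, default_map, rng)
    spec = sk.PedigreeSpec(matings=(
        sk.Mating("child", "sieversii_000", "sieversii_001"),))
    return sk.build_pedigree(spec, panel, truth, rng)
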