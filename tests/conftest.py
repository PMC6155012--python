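import numpy as np
import pandas as pd
import pytest

from mzatlas import synthetic

MIDS = list(synthetic.DEFAULT_MIDS)


@pytest.fixture(scope="session")
def mids():
    return list(MIDS)


@pytest.fixture(scope="session")
def small_repertoire():
    """60-clone single-donor repertoire with chimeras and truth labels."""
    cfg = synthetic.RepertoireSimConfig(n_clones=60, seed=4)
    return synthetic.gen_repertoire(cfg)


@pytest.fixture(scope="session")
def default_repertoire():
    """Study-scale pooled repertoire: four donors, 500 clones each."""
    return synthetic.multi_donor_repertoire(seed=3)


@pytest.fixture(scope="session")
def naive_precursor_table():
    """Naive bubble containing a 10% CD45RB+ precursor subpopulation."""
    arch = [a for a in synthetic.default_archetypes()
            if a.name in ("naive", "precursor")]
    for a in arch:
        a.prevalence = 0.9 if a.name == "naive" else 0.1
    return synthetic.gen_cytometry_sample(arch, 3000, seed=2)


@pytest.fixture(scope="session")
def small_tissue_image():
    """Reduced 160x160 tissue image for fast imaging tests."""
    geom = synthetic.default_tissue_geometry(shape=(160, 160))
    img, chans, truth = synthetic.gen_imc_image(geom, seed=5)
    return geom, img, chans, truth


def two_cloud_table(n=600, seed=0, sep=4.0):
    """Two well-separated archetype clouds on a tiny panel."""
    rng = np.random.default_rng(seed)
    half = n // 2
    markers = ["m1", "m2", "m3"]
    a = rng.normal(0.0, 0.5, size=(half, 3))
    b = rng.normal(sep, 0.5, size=(n - half, 3))
    df = pd.DataFrame(np.vstack([a, b]) + 5.0, columns=markers)
    df["truth_subset"] = ["a"] * half + ["b"] * (n - half)
    from mzatlas.cytometry import EventTable
    return EventTable(df, markers)
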