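import numpy as np
import pytest

from tdgibbs.pedigree import PedigreeEntry


def random_pedigree(n: int, seed: int, n_founders: int = 5, p_founder: float = 0.1):
    """Random multi-generation pedigree with overlapping generations and
    occasional close matings (hence inbreeding)."""
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(n):
        if i < n_founders or rng.random() < p_founder:
            entries.append(PedigreeEntry(f"A{i}"))
        else:
            s = int(rng.integers(0, i))
            d = int(rng.integers(0, i))
            while d == s:
                d = int(rng.integers(0, i))
            entries.append(PedigreeEntry(f"A{i}", f"A{s}", f"A{d}"))
    return entries


@pytest.fixture
def trio():
    """Sire, dam, offspring; parents unrelated."""
    return [
        PedigreeEntry("S"),
        PedigreeEntry("D"),
        PedigreeEntry("X", "S", "D"),
    ]


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated dataset shared by the model-level tests."""
    import tdgibbs as t

    design = t.SimulationDesign(n_cows=60, n_sires=12, n_dams=30, n_herds=3)
    return t.simulate_dataset(design, seed=42)


@pytest.fixture(scope="session")
def small_frame(small_sim):
    import tdgibbs as t

    edited, _ = t.apply_edits(small_sim.records)
    classes = t.assign_classes(edited)
    rel = t.a_inverse(small_sim.pedigree)
    return t.build_model_frame(edited, classes, rel)


@pytest.fixture(scope="session")
def small_store(small_frame):
    """A short covariance chain on the small dataset."""
    import tdgibbs as t

    cfg = t.GibbsConfig(chain_length=300, burn_in=100, thin=2, seed=5)
    return t.run_chain(small_frame, cfg)
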