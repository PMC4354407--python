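import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from methloess import ArraySet, ProbeClass, ProbeManifest
from methloess.simulate import SimulationConfig, simulate_array_set

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


def toy_manifest() -> ProbeManifest:
    """Ten probes covering all classes, a sex chromosome and non-CpG probes."""
    table = pd.DataFrame(
        {
            "probe_class": [
                "I_GREEN", "I_GREEN", "I_GREEN",
                "I_RED", "I_RED", "I_RED",
                "II", "II", "II", "II",
            ],
            "chromosome": ["1", "2", "X", "3", "Y", "4", "5", "X", "6", "7"],
            "is_cpg": [True, True, True, True, True, False, True, True, False, True],
        },
        index=pd.Index([f"cg{i:03d}" for i in range(10)], name="probe_id"),
    )
    return ProbeManifest(table)


@pytest.fixture
def toy_array_set() -> ArraySet:
    rng = np.random.default_rng(42)
    manifest = toy_manifest()
    n = len(manifest)
    M = rng.uniform(500, 5000, size=(n, 4))
    U = rng.uniform(500, 5000, size=(n, 4))
    return ArraySet(M, U, manifest, [f"S{j}" for j in range(4)])


@pytest.fixture(scope="session")
def small_cohort():
    """A small but realistic simulated cohort shared across read-only tests."""
    cfg = SimulationConfig(
        n_probes_p1g=600,
        n_probes_p1r=600,
        n_probes_p2=2800,
        n_samples=8,
        n_replicate_pairs=4,
        n_differential=20,
        n_trait_probes=10,
        seed=123,
    )
    return simulate_array_set(cfg)
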