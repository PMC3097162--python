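import numpy as np
import pytest

import arrayqc as aq

# standard study conditions used across the suite
BASE = dict(n_probesets=200, probes_per_set=4, baseline_sd=0.5)


@pytest.fixture(scope="session")
def small_batch():
    """7-array noisy batch (odd count: median identities are exact)."""
    data, truth = aq.simulate(aq.SimConfig(n_arrays=7, seed=11, **BASE))
    return data, truth


@pytest.fixture(scope="session")
def small_fit(small_batch):
    data, _ = small_batch
    return aq.preprocess(data)


@pytest.fixture(scope="session")
def reference():
    """Frozen reference from a 30-array clean batch on the shared platform."""
    ref_data, _ = aq.simulate(aq.SimConfig(n_arrays=30, seed=990, **BASE))
    return aq.build_reference(ref_data)


@pytest.fixture(scope="session")
def reference_batch():
    ref_data, _ = aq.simulate(aq.SimConfig(n_arrays=30, seed=990, **BASE))
    return ref_data


def tiny_probe_data(values, n_probesets=2, log2_scale=False):
    """Build a minimal ProbeLevelData from a (probes x arrays) array."""
    values = np.asarray(values, dtype=float)
    n_probes, n_arrays = values.shape
    assert n_probes % n_probesets == 0
    per = n_probes // n_probesets
    probe_ids = [f"g{g}_p{p}" for g in range(n_probesets) for p in range(per)]
    return aq.ProbeLevelData(
        intensities=values,
        probe_ids=probe_ids,
        array_ids=[f"a{j}" for j in range(n_arrays)],
        probeset_of={f"g{g}_p{p}": f"g{g}" for g in range(n_probesets)
                     for p in range(per)},
        log2_scale=log2_scale,
    )
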