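import numpy as np
import pandas as pd
import pytest

from epinstab import BetaMatrix, SimConfig, simulate_cohort, simulate_manifest


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig(seed=123, n_probes=1000)


@pytest.fixture(scope="session")
def sim_manifest(sim_cfg):
    manifest, sets = simulate_manifest(sim_cfg)
    return manifest, sets


@pytest.fixture(scope="session")
def cancer_cohort(sim_cfg, sim_manifest):
    manifest, _ = sim_manifest
    return simulate_cohort(sim_cfg, "cancer", manifest)


def make_bm(values: np.ndarray, groups=None, probe_ids=None, sample_ids=None, **annot):
    """Small helper to build a BetaMatrix from a raw array."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    probe_ids = probe_ids or [f"cg{i:04d}" for i in range(n_probes)]
    sample_ids = sample_ids or [f"s{i:02d}" for i in range(n_samples)]
    samples = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    samples["group"] = groups if groups is not None else "normal"
    for k, v in annot.items():
        samples[k] = v
    return BetaMatrix(pd.DataFrame(values, index=probe_ids, columns=sample_ids), samples)
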