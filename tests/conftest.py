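import numpy as np
import pandas as pd
import pytest

from oxiskin.simulate import DeviceProfile, GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study reused across tests (deterministic)."""
    cfg = GeneratorConfig(n_patients=200, n_sites=6, seed=314)
    return generate_dataset(cfg, with_readings=False)


@pytest.fixture(scope="session")
def small_df(small_study):
    return small_study.merged()


@pytest.fixture()
def rng():
    return np.random.default_rng(20220601)


def make_pairs(spo2, sao2, patient_id=None):
    """Minimal observation frame from raw saturation vectors."""
    spo2 = np.asarray(spo2, dtype=float)
    sao2 = np.asarray(sao2, dtype=float)
    n = len(spo2)
    return pd.DataFrame({
        "patient_id": patient_id if patient_id is not None
        else [f"P{i}" for i in range(n)],
        "site_id": "S1",
        "device_model": "D1",
        "spo2_pct": spo2,
        "sao2_pct": sao2,
        "haemoglobin_g_per_l": 100.0,
        "sample_index": np.arange(n),
    })


@pytest.fixture()
def identity_device():
    return DeviceProfile("ident", 95.0, 0.0, 0.0, noise_sd_pp=0.0)
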