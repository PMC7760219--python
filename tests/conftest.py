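import numpy as np
import pytest

import thresholdsire as ts
from thresholdsire.simulate import SimConfig, simulate_pedigree, simulate_records, sire_map


def random_pedigree(n: int, rng: np.random.Generator) -> ts.Pedigree:
    """Random acyclic pedigree: each individual's parents drawn from earlier
    individuals (or unknown)."""
    ids = [f"I{i}" for i in range(n)]
    sires, dams = [], []
    for i in range(n):
        if i < 2 or rng.uniform() < 0.25:
            sires.append("0")
        else:
            sires.append(ids[rng.integers(0, i)])
        if i < 2 or rng.uniform() < 0.25:
            dams.append("0")
        else:
            dams.append(ids[rng.integers(0, i)])
    return ts.Pedigree(ids, sires, dams)


@pytest.fixture(scope="session")
def small_sim():
    """One small study-shaped dataset shared across tests (known truth)."""
    cfg = SimConfig(n_herds=8, n_cows=250, n_sires=40, n_base_dams=200, seed=42)
    ped = simulate_pedigree(cfg)
    teat, prod, truth = simulate_records(cfg, ped)
    stacked = ts.stack_datasets(teat, prod, sire_map(ped))
    return {"cfg": cfg, "ped": ped, "teat": teat, "prod": prod,
            "truth": truth, "stacked": stacked}


@pytest.fixture(scope="session")
def short_fit(small_sim):
    """A short shared chain on the small dataset (for structural checks, not
    for recovery assertions)."""
    model = ts.ThresholdSireModel(small_sim["stacked"], small_sim["ped"], trait="TS")
    return model.fit(n_iter=600, burn_in=200, thin=2, seed=9)
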