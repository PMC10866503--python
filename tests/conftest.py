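import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from parevol import simulate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from parevol.diffexpr import CountMatrix


@pytest.fixture(scope="session")
def small_study():
    """A complete synthetic study, shared across ASE/pipeline tests."""
    scenario = simulate.RegulatoryScenario(
        n_genes=300,
        seed=3,
        mode_fractions={
            "cis_only": 0.2, "trans_only": 0.2, "cis_plus_trans": 0.1,
            "cis_times_trans": 0.1, "compensatory": 0.1, "conserved": 0.3,
        },
    )
    return simulate.simulate_study(scenario)


@pytest.fixture(scope="session")
def null_study():
    """A conserved-only (no regulatory divergence) study."""
    scenario = simulate.RegulatoryScenario(
        n_genes=400, seed=17, mode_fractions={"conserved": 1.0}
    )
    return simulate.simulate_study(scenario)


def make_count_matrix(counts, strains, **meta_cols):
    """CountMatrix from a plain array and per-sample strain labels."""
    counts = np.asarray(counts)
    genes = [f"g{i:03d}" for i in range(counts.shape[0])]
    samples = [f"s{j}" for j in range(counts.shape[1])]
    meta = pd.DataFrame({"strain": strains}, index=samples)
    meta["generation"] = meta_cols.get("generation", "parent")
    for key, val in meta_cols.items():
        meta[key] = val
    return CountMatrix(
        pd.DataFrame(counts, index=genes, columns=samples), meta
    )
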