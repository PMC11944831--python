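import numpy as np
import pandas as pd
import pytest

from tppkit.nparc import nparc_table
from tppkit.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def null_nparc_results():
    """NPARC results for a 1000-protein simulation with no true shifts.

    Shared by the type-I-error and p-value-calibration checks; the fit step
    dominates the cost, so it runs once per session.
    """
    cfg = SimulationConfig(n_proteins=1000, noise_sd=0.05, shift_fraction=0.0, seed=1)
    melt, truth = simulate_dataset(cfg)
    theoretical = nparc_table(melt)
    empirical = theoretical.copy()
    # recompute only the calibration layer on the same RSS values
    from scipy import stats as sps

    from tppkit.nparc import bh_adjust, empirical_df

    mask = empirical["testable"].to_numpy()
    diff = (empirical.loc[mask, "rss0"] - empirical.loc[mask, "rss1"]).to_numpy(float)
    r1 = empirical.loc[mask, "rss1"].to_numpy(float)
    d1, s2n, d2, s2d = empirical_df(diff, r1)
    f_emp = (np.maximum(diff, 0.0) / (d1 * s2n)) / (r1 / (d2 * s2d))
    empirical.loc[mask, "p_value"] = sps.f.sf(f_emp, d1, d2)
    empirical.loc[mask, "p_adjusted"] = bh_adjust(empirical.loc[mask, "p_value"].to_numpy())
    return {"theoretical": theoretical, "empirical": empirical, "truth": truth}


@pytest.fixture(scope="session")
def small_noiseless():
    """20 proteins, no noise, no shifts: exact self-consistency fixture."""
    cfg = SimulationConfig(
        n_proteins=20, noise_sd=0.0, shift_fraction=0.0, n_replicates=1, seed=7
    )
    return simulate_dataset(cfg)
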