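import numpy as np
import pandas as pd
import pytest

import revokit as rk


@pytest.fixture
def toy_masked_freqs():
    """3 populations x 4 loci with hand-enumerable filter behaviour.

    L1 is clean and polymorphic; L2 is missing in two populations (dropped
    at the locus-missingness stage); L3 has one missing value imputed to the
    median of the other two; L4 becomes constant 1.0 after imputation
    (dropped as monomorphic).
    """
    freqs = pd.DataFrame(
        {
            "L1": [0.1, 0.5, 0.9],
            "L2": [0.4, np.nan, np.nan],
            "L3": [0.2, 0.4, np.nan],
            "L4": [1.0, np.nan, 1.0],
        },
        index=["pA", "pB", "pC"],
    )
    return rk.FrequencyMatrix(freqs=freqs)


def make_cline_dataset(rep: int, n_pops: int = 40, n_loci: int = 200,
                       frac_adaptive: float = 0.1, driver: str = "X"):
    """Strong-cline study conditions: unit-range gradients, slopes in [4, 8],
    10% adaptive loci all responding to one predictor, 25-tree pools at 25x."""
    grid = rk.make_climate_grid(
        20, 20, ["X", "Y", "Z"], 4.0, seed=100 + rep,
        ranges={"X": (0, 1), "Y": (0, 1), "Z": (0, 1)})
    pops = rk.sample_populations(grid, n_pops, seed=200 + rep)
    counts, truth = rk.simulate_pool_counts(
        pops, n_loci, frac_adaptive, (4.0, 8.0), 25, 25.0,
        seed=300 + rep, driver=driver if frac_adaptive > 0 else None)
    fm = rk.counts_to_freqs(counts)
    filtered, _ = rk.filter_chain(fm)
    env = pops.loc[filtered.populations].drop(columns=["cell", "x", "y"])
    return filtered, env, truth


@pytest.fixture(scope="session")
def fitted_cline_model():
    """One fitted turnover model on the strong-cline conditions (cached)."""
    filtered, env, truth = make_cline_dataset(0)
    results = rk.TurnoverForest(filtered, env, n_trees=200).fit(seed=400)
    return results, filtered, env, truth
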