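from pathlib import Path

import numpy as np
import pandas as pd
import pytest

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def loess_oracle():
    """Reference smoother output frozen from an independent implementation."""
    fits = pd.read_csv(DATA_DIR / "loess_oracle.csv")
    preds = pd.read_csv(DATA_DIR / "loess_oracle_pred.csv")
    return fits, preds


@pytest.fixture(scope="session")
def truth_level_panel():
    """A noiseless analysis panel built from generator truth only.

    Uses the planted per-genotype truth (expression %, noise %, fitness)
    without simulating measurements, so analysis-level behaviour can be
    tested without pipeline noise.
    """
    from noisefit.synthetic_data import gen_study_panel

    panel = gen_study_panel(43, noise_effect=0.001, seed=11,
                            generate_events=False)
    t = panel.truth
    return pd.DataFrame({
        "genotype": t["genotype_id"],
        "median_expression_pct": t["expr_pct_true"],
        "noise_pct": t["noise_pct_true"],
        "fitness": t["w_true"],
    }), panel


@pytest.fixture(scope="session")
def processed_panel():
    """A small end-to-end processed panel (events -> tables), shared
    across tests to keep the suite fast."""
    from noisefit.pipeline import analysis_panel
    from noisefit.synthetic_data import gen_study_panel

    panel = gen_study_panel(
        24, noise_effect=0.001, seed=7, n_events=4000,
        n_expression_replicates=4, n_fitness_replicates=6)
    return analysis_panel(panel, min_cells=1000), panel
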