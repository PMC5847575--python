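"""Shared fixtures: toy tables and seeded synthetic campaigns."""

import numpy as np
import pandas as pd
import pytest

from diaq import LongReport, TruthParams, simulate


@pytest.fixture
def toy_report_df() -> pd.DataFrame:
    """2 runs × 2 precursors, all fields valid."""
    return pd.DataFrame(
        {
            "run_id": ["r1", "r1", "r2", "r2"],
            "precursor_id": ["p1", "p2", "p1", "p2"],
            "protein_id": ["A", "A", "A", "A"],
            "intensity": [10.0, 20.0, 12.0, 24.0],
            "qvalue": [0.001, 0.002, 0.001, 0.003],
            "rt_observed": [100.0, 200.0, 101.0, 203.0],
            "is_standard": [False, False, False, False],
        }
    )


@pytest.fixture
def toy_report(toy_report_df) -> LongReport:
    return LongReport(toy_report_df)


def make_report(values: pd.DataFrame, qvalue: float = 0.001) -> LongReport:
    """Build a LongReport from a runs × precursors intensity frame."""
    tidy = (
        values.rename_axis("run_id")
        .reset_index()
        .melt(id_vars="run_id", var_name="precursor_id", value_name="intensity")
        .dropna(subset=["intensity"])
    )
    tidy["protein_id"] = "PROT_" + tidy["precursor_id"].astype(str)
    tidy["qvalue"] = qvalue
    tidy["rt_observed"] = np.nan
    tidy["is_standard"] = False
    return LongReport(tidy.reset_index(drop=True))


@pytest.fixture(scope="session")
def small_dataset():
    """A fast 3-batch campaign: 10 strains × 6 replicates plus QCs (~70 runs)."""
    return simulate(TruthParams(n_proteins=40, n_strains=10,
                                replicates_per_strain=6, seed=7))


@pytest.fixture(scope="session")
def default_dataset():
    """The full-scale default campaign (≈330 runs, 3 batches)."""
    return simulate(TruthParams(seed=11))


@pytest.fixture(scope="session")
def batch_free_dataset():
    """Same campaign with batch effects switched off (additive 0, delta² ≈ 1)."""
    return simulate(TruthParams(seed=11, batch_add_sd=0.0,
                                batch_mult_shape=1e6))
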