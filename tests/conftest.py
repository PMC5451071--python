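import numpy as np
import pandas as pd
import pytest

from tcellassay import (
    BASELINE,
    ReadoutKind,
    calibration_preset,
    classify_cohort,
    simulate_cohort,
    wells_to_frame,
)


@pytest.fixture(scope="session")
def calibration_run():
    """The reference synthetic cohort, simulated and classified once."""
    config = calibration_preset()
    wells, truth = simulate_cohort(config)
    calls = classify_cohort(wells)
    return config, wells, truth, calls


def make_wells(groups):
    """Build a wells frame from {(donor, compound, readout): values} plus cells/well.

    ``groups`` maps (donor_id, compound, readout, cells_per_well) -> list of values.
    """
    rows = []
    for (donor, compound, readout, cells), values in groups.items():
        for i, v in enumerate(values, start=1):
            rows.append((donor, compound, ReadoutKind(readout).value, i, float(v), cells))
    return wells_to_frame(
        pd.DataFrame(
            rows,
            columns=["donor_id", "compound", "readout", "replicate", "value", "cells_per_well"],
        )
    )


@pytest.fixture
def one_donor_wells():
    """A single donor with day-matched baselines and one clear responder compound."""
    rng = np.random.default_rng(7)
    base6 = 1000 + 50 * rng.standard_normal(6)
    base8 = 1200 + 50 * rng.standard_normal(6)
    base_es = [4.0, 5.0, 6.0]
    groups = {
        ("d1", BASELINE, "prolif_d6", 100_000): base6,
        ("d1", BASELINE, "prolif_d8", 100_000): base8,
        ("d1", BASELINE, "elispot", 500_000): base_es,
        ("d1", "KLH", "prolif_d6", 100_000): base6 * 8,
        ("d1", "KLH", "prolif_d8", 100_000): base8 * 8,
        ("d1", "KLH", "elispot", 500_000): [60.0, 70.0, 80.0],
        ("d1", "drugA", "prolif_d6", 100_000): base6 * 1.01,
        ("d1", "drugA", "prolif_d8", 100_000): base8 * 0.99,
        ("d1", "drugA", "elispot", 500_000): [5.0, 4.0, 6.0],
    }
    return make_wells(groups)
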