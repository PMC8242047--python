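"""Shared fixtures: small tables and pre-simulated clades.

Expensive simulated datasets are session-scoped so several tests can
reuse them.  All randomness is seeded.
"""

from __future__ import annotations

import numpy as np
import pytest

from fossilbd import (
    OccurrenceRecord,
    OccurrenceTable,
    PreservationModel,
    SimulationRegime,
    default_stage_grid,
    resample_ages,
    sample_fossils,
    simulate_history,
)


def find_history(regime, n_lo, n_hi, seed_start=1, seed_stop=500,
                 require_extinct=False):
    """Scan seeds for a clade whose size falls in [n_lo, n_hi]."""
    for s in range(seed_start, seed_stop):
        h = simulate_history(regime, seed=s)
        if n_lo <= h.n_species <= n_hi:
            if require_extinct and h.extant.any():
                continue
            return h
    raise RuntimeError("no acceptable simulation found in seed range")


@pytest.fixture
def toy_table():
    recs = [
        OccurrenceRecord("Alpha_one", 70.0, 75.0, region="new_world",
                         clade="fam1"),
        OccurrenceRecord("Alpha_one", 66.5, 71.0, region="new_world",
                         clade="fam1"),
        OccurrenceRecord("Beta_two", 67.0, 72.1, region="old_world",
                         clade="fam2"),
        OccurrenceRecord("Gamma_three", 80.0, 83.6, region="other",
                         clade="fam1"),
    ]
    return OccurrenceTable(recs, "toy")


@pytest.fixture(scope="session")
def stage_grid():
    return default_stage_grid()


@pytest.fixture(scope="session")
def constant_clade():
    """Fully extinct clade under constant rates, ~100-300 species."""
    reg = SimulationRegime(kind="piecewise", origin_age=120, end_age=10,
                           lam=[0.15], mu=[0.15], shift_times=[])
    return find_history(reg, 100, 300, require_extinct=True)


@pytest.fixture(scope="session")
def constant_dataset(constant_clade):
    pm = PreservationModel(kind="HPP", q=3.0)
    table = sample_fossils(constant_clade, pm, seed=999)
    rep = resample_ages(table, 1, seed=5)[0]
    return constant_clade, table, rep
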