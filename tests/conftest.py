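"""Shared fixtures: reference parameters and the scaled-down recovery study.

Expensive objects (synthetic datasets, the noise-free joint fit) are
session-scoped so the acceptance checks and the unit-level diagnostics
share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from fourpool.fitting import FourPoolModel
from fourpool.propagation import effective_flip_table
from fourpool.protocols import reduced_suite
from fourpool.synthetic import (
    EchoTrainDataset,
    reference_ci95,
    reference_parameters,
    simulate_suite,
)


@pytest.fixture(scope="session")
def series():
    return reference_parameters()


@pytest.fixture(scope="session")
def p35(series):
    return series.at(35.0)


@pytest.fixture(scope="session")
def ci95():
    return reference_ci95()


@pytest.fixture(scope="session")
def reduced_setup(series):
    """Reduced suite, its effective-flip tables and the noise-free dataset."""
    suite = reduced_suite()
    events = [ev for p in suite for ev in p.rf_events()]
    flips = {t: effective_flip_table(events, series.at(t))
             for t in series.temperatures_c}
    clean = simulate_suite(series, suite, flips=flips)
    ds = EchoTrainDataset(frame=clean, flips=flips)
    return suite, flips, ds


@pytest.fixture(scope="session")
def recovery_fit(series, reduced_setup):
    """Noise-free joint 4PM fit from a +-10% perturbed start.

    Multi-start (the guard against the local minima of the 44-parameter
    problem) with a short per-start evaluation cap: a start that has not
    collapsed toward zero cost within the cap is abandoned.
    """
    suite, flips, ds = reduced_setup
    model = FourPoolModel(ds, suite=suite, flips=flips)
    result = model.fit(series, perturb=0.10, seed=1, n_starts=8,
                       max_nfev=40, early_stop_cost=1e-12)
    return model, result
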