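"""Shared fixtures.

The expensive end-to-end artifacts (scenario STRFs, the reduced GA recovery
run, the two-state demo) are session-scoped so that several tests can assert
different properties of one computation.
"""

import numpy as np
import pytest

from strfnet.network import Genome
from strfnet.optimize import EvalContext, GAConfig, evaluate_strf, run_ga
from strfnet.periphery import cf_grid
from strfnet.pipeline import RunConfig, two_state_demo
from strfnet.scenarios import make_scenario, make_target
from strfnet.torc import dynamic_spectrum, make_torc_set


@pytest.fixture(scope="session")
def bank15():
    return cf_grid(15)


@pytest.fixture(scope="session")
def torc30_dspecs(bank15):
    """A study-sized 30-TORC set and its dynamic spectra."""
    specs = make_torc_set(30, bank15.axis(), seed=11)
    return [dynamic_spectrum(s) for s in specs]


@pytest.fixture(scope="session")
def scenario_results():
    """All six checkable scenarios run end-to-end at 30 TORCs x 4 reps."""
    out = {}
    for name in (
        "excit_5k",
        "excit_2k5",
        "inhib_5k",
        "excit_5k_delay55",
        "lateral_inhib",
        "lateral_excit",
    ):
        sc = make_scenario(name)
        target, _ = make_target(sc, seed=0)
        out[name] = (sc, target)
    return out


@pytest.fixture(scope="session")
def small_ctx():
    """Tiny 5-neuron evaluation context for GA/sensitivity unit tests."""
    return EvalContext.build(
        n_neurons=5, n_torcs=4, reps=1, seed=42, duration_s=1.0, tonic_rate_hz=0.0
    )


@pytest.fixture(scope="session")
def small_gt(small_ctx):
    """Ground-truth genome and its target STRF in the small context."""
    gt = Genome.zeros(5)
    istr = gt.istr.copy()
    idel = gt.idel.copy()
    istr[2] = 5
    idel[2] = -4
    gt = Genome(gt.w.copy(), istr, idel)
    target = evaluate_strf(gt, small_ctx, 2)
    return gt, target


@pytest.fixture(scope="session")
def reduced_recovery():
    """Reduced-scale GA recovery: 5 neurons, population 60, 15 generations."""
    ctx = EvalContext.build(n_neurons=5, n_torcs=10, reps=1, seed=7, duration_s=1.0)
    gt = Genome.zeros(5)
    istr = gt.istr.copy()
    idel = gt.idel.copy()
    w = gt.w.copy()
    istr[2] = 5
    idel[2] = -4
    istr[1] = 4
    idel[1] = -4
    w[1, 2] = -3
    gt = Genome(w, istr, idel)
    target = evaluate_strf(gt, ctx, 2)
    result = run_ga(target, GAConfig.reduced(seed=3), ctx)
    return {"ctx": ctx, "gt": gt, "target": target, "result": result}


@pytest.fixture(scope="session")
def demo_result():
    """End-to-end two-state comparison demo (5 repeats)."""
    result, changed = two_state_demo(RunConfig(master_seed=0))
    return result, changed
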