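"""Integration engine: sampling grid, determinism, events, noise and
numerical convergence."""

import numpy as np
import pytest

import cardiouq as cq
from cardiouq.biomarkers import extract
from cardiouq.simulation import add_noise, prepace, run, simulate_synthetic


def test_sample_count_arithmetic(br_model):
    proto = cq.make_protocol("single_ap")
    trace = run(br_model, None, proto)
    assert len(trace) == int(np.floor(1000.0 / 0.2)) + 1
    assert np.allclose(np.diff(trace.times), 0.2)


def test_trace_reproducible_bit_for_bit(br_model):
    proto = cq.make_protocol("single_ap")
    a = run(br_model, None, proto)
    b = run(br_model, None, proto)
    assert np.array_equal(a.voltages, b.voltages)


def test_synthetic_trace_reproducible(br_model):
    proto = cq.make_protocol("single_ap")
    a = simulate_synthetic(br_model, proto, sigma=0.25, seed=5, n_prepace=2)
    b = simulate_synthetic(br_model, proto, sigma=0.25, seed=5, n_prepace=2)
    assert np.array_equal(a.voltages, b.voltages)


def test_sodium_knockout_suppresses_upstroke(br_model):
    """Zeroing G_Na reduces the post-stimulus upstroke velocity by >10x."""
    proto = cq.make_protocol("single_ap")
    full = run(br_model, None, proto)
    params = cq.scale_conductances(br_model, br_model.defaults, {"G_Na": 0.0})
    ko = run(br_model, params, proto)

    def max_dvdt_10ms(tr):
        w = tr.window(1.0, 9.0)  # post-stimulus
        return np.max(np.gradient(w.voltages, tr.sample_interval))

    assert max_dvdt_10ms(ko) < 0.1 * max_dvdt_10ms(full)


def test_knockout_event_changes_second_beat(tt04_model):
    """A G_Kr knockout at 1000 ms leaves beat 1 untouched, prolongs beat 2."""
    proto = cq.make_protocol("knockout", model=tt04_model, knockout_current="G_Kr")
    control = cq.make_protocol("long_pacing", duration=2000.0)
    a = run(tt04_model, None, proto)
    b = run(tt04_model, None, control)
    assert np.allclose(a.window(0, 1000).voltages, b.window(0, 1000).voltages, atol=1e-6)
    apd_ko = extract(a, 1000.0, 1000.0).apd90
    apd_ctrl = extract(b, 1000.0, 1000.0).apd90
    assert apd_ko > apd_ctrl + 5.0


def test_ko_double_changes_only_potassium(tt04_model):
    """Doubling [K+]o is a pure Conditions change: same stimuli, depolarised rest."""
    ko2 = cq.make_protocol("ko_double", model=tt04_model)
    ctrl = cq.make_protocol("single_ap")
    assert [s[:2] for s in ko2.stimulus_times()] == [s[:2] for s in ctrl.stimulus_times()]
    a = run(tt04_model, None, ko2)
    b = run(tt04_model, None, ctrl)
    # higher [K+]o raises E_K, depolarising the resting membrane
    assert a.voltages[-1] > b.voltages[-1] + 2.0


def test_prepace_deterministic_and_converging(tp06_model):
    s1, info1 = prepace(tp06_model, None, 1000.0, 1)
    s1b, _ = prepace(tp06_model, None, 1000.0, 1)
    assert np.array_equal(s1, s1b)
    # one beat from the published state barely moves the bulk ion pools
    # (diastolic Ca_i is a near-zero state, ~1e-4 mM, and swings much more)
    rel = np.abs(s1 - tp06_model.initial_state) / np.maximum(
        np.abs(tp06_model.initial_state), 1e-6
    )
    bulk_pools = [1, 2]  # K_i, Na_i
    assert np.all(rel[bulk_pools] < 0.01)
    _, info5 = prepace(tp06_model, None, 1000.0, 5)
    assert info5["max_rel_state_change"] < info1["max_rel_state_change"] * 2.0


def test_add_noise_properties(br_model):
    proto = cq.make_protocol("single_ap")
    clean = run(br_model, None, proto)
    assert np.array_equal(add_noise(clean, 0.0, seed=1).voltages, clean.voltages)
    a = add_noise(clean, 0.25, seed=9)
    b = add_noise(clean, 0.25, seed=9)
    assert np.array_equal(a.voltages, b.voltages)
    assert not np.array_equal(a.voltages, clean.voltages)


def test_noise_sd_calibration(br_model):
    """Sample sd of the added noise matches sigma to sampling error."""
    rng_trace = run(br_model, None, cq.make_protocol("long_pacing", duration=20_000))
    n = len(rng_trace)
    assert n >= 100_000
    noisy = add_noise(rng_trace, 0.25, seed=123)
    resid = noisy.voltages - rng_trace.voltages
    assert 0.247 <= resid.std(ddof=1) <= 0.253


def test_solver_tolerance_convergence(tp06_model):
    """Halving tolerances moves TP06 biomarkers by < 0.1 ms / 0.1 mV."""
    proto = cq.make_protocol("single_ap")
    a = extract(run(tp06_model, None, proto, rtol=1e-6, atol=1e-8))
    b = extract(run(tp06_model, None, proto, rtol=5e-7, atol=5e-9))
    assert abs(a.apd90 - b.apd90) < 0.1
    assert abs(a.apd50 - b.apd50) < 0.1
    assert abs(a.max_vm - b.max_vm) < 0.1
    assert abs(a.resting_vm - b.resting_vm) < 0.1
    assert abs(a.dome_vm - b.dome_vm) < 0.1
    assert abs(a.max_dvdt - b.max_dvdt) < 0.1


def test_tp06_beat_to_beat_steady_state(tp06_model):
    """20 beats at 1000 ms CL: |APD90(19) - APD90(20)| < 0.5 ms."""
    proto = cq.make_protocol("long_pacing", duration=20_000)
    trace = run(tp06_model, None, proto)
    b19 = extract(trace, 18_000.0, 1000.0)
    b20 = extract(trace, 19_000.0, 1000.0)
    assert abs(b19.apd90 - b20.apd90) < 0.5


def test_initial_state_dimension_check(br_model):
    with pytest.raises(ValueError, match="initial_state"):
        run(br_model, None, cq.make_protocol("single_ap"), initial_state=np.zeros(3))
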