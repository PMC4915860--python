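"""Cell-model registry: published defaults, the common RHS contract, and
per-current decompositions."""

import numpy as np
import pytest

import cardiouq as cq
from cardiouq.models import available_models, get_model
from cardiouq.models.base import ParameterVector, scale_conductances
from cardiouq.simulation import run
from cardiouq.protocols import Protocol, Segment


def test_registry_contains_required_models():
    names = available_models()
    for required in (
        "beeler_reuter_1977",
        "luo_rudy_1991",
        "tentusscher_2004",
        "tentusscher_2006_epi",
    ):
        assert required in names


def test_unknown_model_error_lists_registry():
    with pytest.raises(KeyError, match="beeler_reuter_1977"):
        get_model("hodgkin_huxley_1952")


@pytest.mark.parametrize(
    "model_name, param, expected",
    [
        ("tentusscher_2006_epi", "G_Na", 14.838),
        ("tentusscher_2006_epi", "tau_f_multiplier", 1.0),
        ("tentusscher_2006_epi", "G_Kr", 0.153),
        ("tentusscher_2006_epi", "P_NaK", 2.724),
        ("tentusscher_2004", "G_Na", 14.838),
        ("tentusscher_2004", "k_NaCa", 1000.0),
        ("luo_rudy_1991", "G_Na", 23.0),
        ("beeler_reuter_1977", "G_s", 0.09),
    ],
)
def test_published_default_conductances(model_name, param, expected):
    assert get_model(model_name).defaults[param] == pytest.approx(expected)


def test_model_sizes():
    assert len(get_model("beeler_reuter_1977").parameter_names) == 4
    assert len(get_model("tentusscher_2004").parameter_names) == 12
    assert len(get_model("tentusscher_2006_epi").parameter_names) == 13


@pytest.mark.parametrize("model_name", available_models())
def test_defaults_positive_and_unique(model_name):
    m = get_model(model_name)
    assert len(set(m.parameter_names)) == len(m.parameter_names)
    assert np.all(m.defaults.to_array() > 0)


@pytest.mark.parametrize("model_name", available_models())
def test_initial_state_is_near_steady(model_name):
    """Two unstimulated seconds from the stored state move Vm by < 1 mV."""
    m = get_model(model_name)
    proto = Protocol(
        "quiescent",
        (Segment(period=4000.0, length=2000.0, stim_amplitude=0.0, stim_duration=1.0),),
        sample_interval=10.0,
    )
    trace = run(m, None, proto)
    assert abs(trace.voltages[-1] - trace.voltages[0]) < 1.0


@pytest.mark.parametrize("model_name", available_models())
def test_rhs_matches_current_decomposition(model_name):
    """dV/dt from the RHS equals minus the sum of the decomposed currents."""
    m = get_model(model_name)
    theta = m.defaults.to_array()
    ko = m.default_Ko or 0.0
    y = m.initial_state.copy()
    y[0] = -20.0  # probe at a plateau-like voltage as well as rest
    for state in (m.initial_state, y):
        dy = m.rhs(state, 0.0, theta, ko, 0.0)
        currents = m.ionic_currents(state, theta, ko)
        assert dy[0] == pytest.approx(-sum(currents.values()), rel=1e-10, abs=1e-9)


@pytest.mark.parametrize("model_name", available_models())
def test_zeroed_conductance_removes_current(model_name):
    """With a conductance factor of 0 the total equals the sum of the rest."""
    m = get_model(model_name)
    ko = m.default_Ko or 0.0
    name = m.parameter_names[0]
    zeroed = scale_conductances(m, m.defaults, {name: 0.0})
    full = m.ionic_currents(m.initial_state, m.defaults.to_array(), ko)
    red = m.ionic_currents(m.initial_state, m.parameter_array(zeroed), ko)
    dy = m.rhs(m.initial_state, 0.0, m.parameter_array(zeroed), ko, 0.0)
    assert dy[0] == pytest.approx(-sum(red.values()), rel=1e-10, abs=1e-9)
    # only the scaled current changed
    changed = [k for k in full if abs(full[k] - red[k]) > 1e-12]
    assert len(changed) <= 1


def test_scale_conductances():
    m = get_model("tentusscher_2006_epi")
    base = m.defaults
    assert scale_conductances(m, base, {}).to_array() == pytest.approx(base.to_array())
    ko = scale_conductances(m, base, {"G_Na": 0.0})
    assert ko["G_Na"] == 0.0
    others = [n for n in m.parameter_names if n != "G_Na"]
    for n in others:
        assert ko[n] == base[n]
    half = scale_conductances(m, base, {"G_Kr": 0.5})
    assert half["G_Kr"] == pytest.approx(0.0765)


def test_scale_conductances_errors():
    m = get_model("beeler_reuter_1977")
    with pytest.raises(ValueError, match="non-negative"):
        scale_conductances(m, m.defaults, {"G_Na": -1.0})
    with pytest.raises(ValueError, match="unknown"):
        scale_conductances(m, m.defaults, {"G_Kr": 0.5})


def test_parameter_vector_invariants():
    with pytest.raises(ValueError):
        ParameterVector(["a", "a"], [1.0, 2.0])
    with pytest.raises(ValueError):
        ParameterVector(["a"], [-1.0])
    pv = ParameterVector(["a", "b"], [1.0, 2.0])
    assert pv.replace(b=3.0)["b"] == 3.0
    assert pv["b"] == 2.0  # original untouched


def test_metadata_export(tmp_path):
    import yaml

    m = get_model("tentusscher_2006_epi")
    meta = m.metadata()
    text = yaml.safe_dump(meta)
    back = yaml.safe_load(text)
    assert back["parameters"]["G_Na"]["default"] == pytest.approx(14.838)
    assert back["supports_extracellular_potassium"] is True
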