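"""Common contract for cardiac action-potential cell models.

Every registered model exposes:

* an ordered list of maximal-conductance (or scaling) parameter names with
  published default values ("the conductances that feature in the published
  model"),
* a stiff-solver-ready right hand side ``rhs(y, t, theta, ko, stim)`` returning
  state derivatives per millisecond, with ``theta`` the conductance vector in
  the model's declared order, ``ko`` the extracellular potassium concentration
  in mM (ignored by models without [K+]o support) and ``stim`` the applied
  stimulus current density in pA/pF (negative = depolarising),
* a per-current decomposition ``ionic_currents(y, theta, ko)`` used to verify
  that zeroing a conductance removes exactly that current's contribution.

Units throughout: mV, ms, mM; currents normalised to pA/pF.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "ParameterVector",
    "Conditions",
    "CellModel",
    "scale_conductances",
]


class ParameterVector(Mapping):
    """An ordered, named, non-negative parameter vector (natural units)."""

    def __init__(self, names, values):
        names = list(names)
        values = np.asarray(values, dtype=float)
        if len(names) != values.size:
            raise ValueError("names and values must have equal length")
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("parameter values must be finite and non-negative")
        self._names = names
        self._values = values
        self._index = {n: i for i, n in enumerate(names)}

    @property
    def names(self):
        return list(self._names)

    def to_array(self) -> np.ndarray:
        return self._values.copy()

    def replace(self, **updates) -> "ParameterVector":
        vals = self._values.copy()
        for k, v in updates.items():
            vals[self._index[k]] = v
        return ParameterVector(self._names, vals)

    # Mapping interface
    def __getitem__(self, key):
        return float(self._values[self._index[key]])

    def __iter__(self):
        return iter(self._names)

    def __len__(self):
        return len(self._names)

    def __repr__(self):
        body = ", ".join(f"{n}={v:g}" for n, v in zip(self._names, self._values))
        return f"ParameterVector({body})"


@dataclass(frozen=True)
class Conditions:
    """Fixed extracellular conditions (concentrations in mM)."""

    Ko: float | None = None

    def __post_init__(self):
        if self.Ko is not None and self.Ko <= 0:
            raise ValueError("[K+]o must be positive")


@dataclass(frozen=True)
class CellModel:
    """A cardiac AP ODE model with named conductance parameters theta."""

    name: str
    n_state: int
    state_names: tuple
    parameter_names: tuple
    parameter_units: dict
    defaults: ParameterVector
    initial_state: np.ndarray
    rhs: Callable  # rhs(y, t, theta_array, ko, stim) -> dy/dt
    ionic_currents: Callable  # (y, theta_array, ko) -> dict name -> pA/pF
    default_Ko: float | None
    supports_extracellular_potassium: bool
    stimulus_convention: str = "pA_per_pF"
    default_stimulus: tuple = (-52.0, 1.0)  # (amplitude pA/pF, duration ms)
    reference: str = ""
    notes: str = field(default="", compare=False)

    def default_conditions(self) -> Conditions:
        return Conditions(Ko=self.default_Ko)

    def parameter_array(self, params: ParameterVector | None = None) -> np.ndarray:
        if params is None:
            return self.defaults.to_array()
        missing = [n for n in self.parameter_names if n not in params]
        if missing:
            raise ValueError(f"parameter vector incomplete, missing {missing}")
        return np.array([params[n] for n in self.parameter_names], dtype=float)

    def metadata(self) -> dict:
        """Structured, serialisable description of the model."""
        return {
            "name": self.name,
            "n_state": self.n_state,
            "parameters": {
                n: {"default": self.defaults[n], "units": self.parameter_units.get(n, "")}
                for n in self.parameter_names
            },
            "supports_extracellular_potassium": self.supports_extracellular_potassium,
            "default_Ko_mM": self.default_Ko,
            "stimulus_convention": self.stimulus_convention,
            "reference": self.reference,
        }


def scale_conductances(model: CellModel, base: ParameterVector, factors: Mapping) -> ParameterVector:
    """Return a copy of ``base`` with named entries multiplied by ``factors``.

    Supports knockout (factor 0) and pharmacological block protocols.
    """
    unknown = [k for k in factors if k not in model.parameter_names]
    if unknown:
        raise ValueError(f"unknown parameters {unknown}; model has {list(model.parameter_names)}")
    for k, f in factors.items():
        if f < 0:
            raise ValueError(f"conductance factor for {k} must be non-negative, got {f}")
    return base.replace(**{k: base[k] * f for k, f in factors.items()})
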