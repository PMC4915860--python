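"""Experimental protocol library.

A :class:`Protocol` is an ordered list of pacing segments (pacing period,
stimulus amplitude/duration, segment length) plus a list of timed events that
change a conductance factor or the extracellular potassium concentration
mid-run. Events are applied as instantaneous changes; the integrator is
restarted at event times.

Protocol kinds:

``single_ap``     one stimulus at t = 0, 1000 ms window (one full 1 Hz cycle);
``ko_half``       single AP with [K+]o halved from t = 0;
``ko_double``     single AP with [K+]o doubled from t = 0;
``s1s2``          1000 ms at 1 Hz then 1000 ms at 2 Hz (three APs in 2000 ms);
``knockout``      2000 ms at 1 Hz, one conductance set to zero at 1000 ms;
``long_pacing``   1 Hz pacing for a caller-chosen duration (e.g. 10 or 20 s).

Pharmacological block is modelled as conductance scaling by
1 / (1 + (C / IC50)^h) with Hill coefficient h (default 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .models.base import CellModel, ParameterVector

__all__ = [
    "Segment",
    "Event",
    "Protocol",
    "DrugBlock",
    "make_protocol",
    "apply_drug_block",
    "pic50_to_ic50",
]

DEFAULT_SAMPLE_INTERVAL = 0.2  # ms
DEFAULT_STIM_AMPLITUDE = -52.0  # pA/pF
DEFAULT_STIM_DURATION = 1.0  # ms


@dataclass(frozen=True)
class Segment:
    """A pacing segment: stimuli at the start of every ``period``-ms cycle."""

    period: float  # ms between stimuli
    length: float  # ms of this segment
    stim_amplitude: float = DEFAULT_STIM_AMPLITUDE  # pA/pF (negative = depolarising)
    stim_duration: float = DEFAULT_STIM_DURATION  # ms

    def __post_init__(self):
        if self.period <= 0 or self.length <= 0:
            raise ValueError("segment period and length must be positive")
        if not 0 < self.stim_duration < self.period:
            raise ValueError("stimulus duration must lie within the pacing period")


@dataclass(frozen=True)
class Event:
    """A timed instantaneous change of model conditions.

    ``action`` is ``"set_conductance_factor"`` (with ``name``/``value``) or
    ``"set_Ko"`` (with ``value`` in mM).
    """

    time: float
    action: str
    value: float
    name: str | None = None

    def __post_init__(self):
        if self.action not in ("set_conductance_factor", "set_Ko"):
            raise ValueError(f"unknown event action {self.action!r}")
        if self.action == "set_conductance_factor" and self.name is None:
            raise ValueError("set_conductance_factor event requires a parameter name")
        if self.action == "set_conductance_factor" and self.value < 0:
            raise ValueError("conductance factor must be non-negative")
        if self.action == "set_Ko" and self.value <= 0:
            raise ValueError("[K+]o must be positive")


@dataclass(frozen=True)
class Protocol:
    kind: str
    segments: tuple
    events: tuple = ()
    sample_interval: float = DEFAULT_SAMPLE_INTERVAL

    def __post_init__(self):
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        for ev in self.events:
            if not 0 <= ev.time <= self.total_duration:
                raise ValueError(f"event at t={ev.time} ms outside [0, {self.total_duration}] ms")

    @property
    def total_duration(self) -> float:
        return sum(s.length for s in self.segments)

    def stimulus_times(self) -> list[tuple[float, float, float]]:
        """All stimuli as (onset ms, duration ms, amplitude pA/pF)."""
        out = []
        t0 = 0.0
        for seg in self.segments:
            t = 0.0
            while t < seg.length - 1e-9:
                out.append((t0 + t, seg.stim_duration, seg.stim_amplitude))
                t += seg.period
            t0 += seg.length
        return out

    def with_sample_interval(self, dt: float) -> "Protocol":
        return replace(self, sample_interval=dt)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "sample_interval": self.sample_interval,
            "segments": [
                {
                    "period": s.period,
                    "length": s.length,
                    "stim_amplitude": s.stim_amplitude,
                    "stim_duration": s.stim_duration,
                }
                for s in self.segments
            ],
            "events": [
                {"time": e.time, "action": e.action, "name": e.name, "value": e.value}
                for e in self.events
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Protocol":
        return cls(
            kind=d.get("kind", "custom"),
            segments=tuple(Segment(**s) for s in d["segments"]),
            events=tuple(Event(**e) for e in d.get("events", [])),
            sample_interval=d.get("sample_interval", DEFAULT_SAMPLE_INTERVAL),
        )


PROTOCOL_KINDS = ("single_ap", "ko_half", "ko_double", "s1s2", "knockout", "long_pacing")


def make_protocol(
    kind: str,
    model: CellModel | None = None,
    *,
    knockout_current: str | None = None,
    duration: float | None = None,
    stim_amplitude: float = DEFAULT_STIM_AMPLITUDE,
    stim_duration: float = DEFAULT_STIM_DURATION,
    sample_interval: float = DEFAULT_SAMPLE_INTERVAL,
) -> Protocol:
    """Construct one of the library protocols.

    ``model`` is required for the [K+]o protocols (to resolve the control
    [K+]o and check applicability) and for knockout (to validate the name).
    """
    if kind not in PROTOCOL_KINDS:
        raise ValueError(f"unknown protocol kind {kind!r}; choose from {PROTOCOL_KINDS}")

    one_hz = dict(period=1000.0, stim_amplitude=stim_amplitude, stim_duration=stim_duration)

    if kind == "single_ap":
        return Protocol(kind, (Segment(length=1000.0, **one_hz),), sample_interval=sample_interval)

    if kind in ("ko_half", "ko_double"):
        if model is None:
            raise ValueError(f"{kind} requires a model to resolve the control [K+]o")
        if not model.supports_extracellular_potassium or model.default_Ko is None:
            raise ValueError(
                f"{kind} not applicable: model {model.name!r} has no [K+]o dependence"
            )
        factor = 0.5 if kind == "ko_half" else 2.0
        ev = Event(time=0.0, action="set_Ko", value=model.default_Ko * factor)
        return Protocol(
            kind, (Segment(length=1000.0, **one_hz),), events=(ev,), sample_interval=sample_interval
        )

    if kind == "s1s2":
        s1 = Segment(length=1000.0, **one_hz)
        s2 = Segment(
            period=500.0,
            length=1000.0,
            stim_amplitude=stim_amplitude,
            stim_duration=stim_duration,
        )
        return Protocol(kind, (s1, s2), sample_interval=sample_interval)

    if kind == "knockout":
        if knockout_current is None:
            raise ValueError("knockout protocol requires knockout_current (a conductance name)")
        if model is not None and knockout_current not in model.parameter_names:
            raise ValueError(
                f"cannot knock out {knockout_current!r}: not a parameter of {model.name!r} "
                f"({list(model.parameter_names)})"
            )
        ev = Event(time=1000.0, action="set_conductance_factor", name=knockout_current, value=0.0)
        return Protocol(
            kind, (Segment(length=2000.0, **one_hz),), events=(ev,), sample_interval=sample_interval
        )

    # long_pacing
    if duration is None:
        raise ValueError("long_pacing requires duration (ms)")
    if duration < 1000.0:
        raise ValueError("long_pacing duration must cover at least one 1 Hz cycle")
    return Protocol(kind, (Segment(length=float(duration), **one_hz),), sample_interval=sample_interval)


@dataclass(frozen=True)
class DrugBlock:
    """Simple pore-block model of a compound acting on one current."""

    concentration: float  # uM
    ic50: float  # uM
    hill: float = 1.0

    def __post_init__(self):
        if self.ic50 <= 0:
            raise ValueError("IC50 must be positive")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.hill <= 0:
            raise ValueError("Hill coefficient must be positive")

    @property
    def factor(self) -> float:
        """Remaining fractional conductance, 1 / (1 + (C/IC50)^h)."""
        return 1.0 / (1.0 + (self.concentration / self.ic50) ** self.hill)


def _resolve_parameter(name: str, params: ParameterVector) -> str:
    """Map a current name like ``I_Kr`` to its conductance parameter."""
    if name in params:
        return name
    if name.startswith("I_"):
        for prefix in ("G_", "P_", "k_"):
            cand = prefix + name[2:]
            if cand in params:
                return cand
    raise ValueError(f"no conductance parameter for current {name!r} in {params.names}")


def apply_drug_block(params: ParameterVector, blocks) -> ParameterVector:
    """Scale each named current's conductance by its block factor.

    ``blocks`` is an iterable of (current-or-parameter name, DrugBlock).
    """
    updates = {}
    for name, block in blocks:
        pname = _resolve_parameter(name, params)
        updates[pname] = params[pname] * block.factor
    return params.replace(**updates)


def pic50_to_ic50(pic50: float) -> float:
    """Convert pIC50 (= -log10 IC50 in molar) to IC50 in uM."""
    return 10.0 ** (6.0 - pic50)
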