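"""File formats and run configuration.

All artifacts are delimited text with a ``#``-prefixed YAML metadata header,
so every file records the configuration and seeds that produced it.

Trace files are two columns (time ms, Vm mV); the reader accepts any uniform
sampling (e.g. the 250 us spacing of 4 kHz patch-clamp recordings) and
rejects non-uniform files naming the first offending row.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .emulator import DesignData, InputSpec
from .inference import PosteriorChain
from .simulation import VoltageTrace

__all__ = [
    "read_trace",
    "write_trace",
    "save_chain",
    "load_chain",
    "save_design",
    "load_design",
    "RunConfig",
]


def _write_header(fh, meta: dict):
    text = yaml.safe_dump(meta, sort_keys=False)
    for line in text.rstrip("\n").split("\n"):
        fh.write(f"# {line}\n")


def _read_header(path) -> dict:
    lines = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            lines.append(line[1:].lstrip())
    try:
        meta = yaml.safe_load("".join(lines)) if lines else {}
    except yaml.YAMLError:
        meta = {}
    return meta if isinstance(meta, dict) else {}


def write_trace(trace: VoltageTrace, path):
    path = Path(path)
    meta = dict(trace.meta)
    meta.update(
        {
            "start_time_ms": trace.start_time,
            "sample_interval_ms": trace.sample_interval,
            "n_samples": len(trace),
        }
    )
    with open(path, "w") as fh:
        _write_header(fh, meta)
        np.savetxt(fh, np.column_stack([trace.times, trace.voltages]), fmt="%.10g")


def read_trace(path) -> VoltageTrace:
    """Read a two-column (time ms, Vm mV) delimited text trace.

    The sample interval is inferred from the time column and must be uniform
    to a relative tolerance of 1e-6.
    """
    path = Path(path)
    meta = _read_header(path)
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two numeric columns (time, Vm)")
    if data.shape[0] < 2:
        raise ValueError(f"{path}: a voltage trace needs at least 2 samples")
    t, v = data[:, 0], data[:, 1]
    dt = t[1] - t[0]
    if dt <= 0:
        raise ValueError(f"{path}: non-increasing time at row 2")
    steps = np.diff(t)
    bad = np.nonzero(np.abs(steps - dt) > 1e-6 * max(abs(dt), 1.0))[0]
    if bad.size:
        row = int(bad[0]) + 2  # 1-based, offending row
        raise ValueError(
            f"{path}: non-uniform sampling at row {row} "
            f"(step {steps[bad[0]]:.9g} ms vs {dt:.9g} ms)"
        )
    return VoltageTrace(float(t[0]), float(dt), v, meta)


def save_chain(chain: PosteriorChain, path):
    path = Path(path)
    meta = {
        "parameter_names": list(chain.names),
        "acceptance_rate": chain.acceptance_rate,
        "seed": chain.seed,
        "burn_in": chain.burn_in,
        "stride": chain.stride,
    }
    meta.update(chain.meta)
    with open(path, "w") as fh:
        _write_header(fh, meta)
        fh.write("# columns: " + " ".join([*chain.names, "log_posterior"]) + "\n")
        np.savetxt(fh, np.column_stack([chain.samples, chain.log_pdfs]), fmt="%.10g")


def load_chain(path) -> PosteriorChain:
    path = Path(path)
    meta = _read_header(path)
    data = np.loadtxt(path, comments="#", ndmin=2)
    names = tuple(meta.pop("parameter_names"))
    return PosteriorChain(
        names=names,
        samples=data[:, : len(names)],
        log_pdfs=data[:, len(names)],
        acceptance_rate=float(meta.pop("acceptance_rate", np.nan)),
        seed=meta.pop("seed", None),
        burn_in=float(meta.pop("burn_in", 0.0)),
        stride=int(meta.pop("stride", 1)),
        meta=meta,
    )


def save_design(design: DesignData, path):
    path = Path(path)
    names = list(design.spec.names)
    out_names = list(design.outputs)
    meta = {
        "input_names": names,
        "input_centres": [float(c) for c in design.spec.centres],
        "output_names": out_names,
        "seed": design.seed,
        "n_runs": design.n,
        "failures": [list(f) for f in design.failures],
    }
    cols = [design.inputs] + [design.outputs[k][:, None] for k in out_names]
    cols.append(design.apd90_beat19[:, None])
    with open(path, "w") as fh:
        _write_header(fh, meta)
        fh.write("# columns: " + " ".join(names + out_names + ["apd90_beat19"]) + "\n")
        np.savetxt(fh, np.hstack(cols), fmt="%.10g")


def load_design(path) -> DesignData:
    path = Path(path)
    meta = _read_header(path)
    data = np.loadtxt(path, comments="#", ndmin=2)
    names = tuple(meta["input_names"])
    out_names = list(meta["output_names"])
    d = len(names)
    spec = InputSpec(names, np.asarray(meta["input_centres"], float))
    outputs = {k: data[:, d + i] for i, k in enumerate(out_names)}
    return DesignData(
        spec=spec,
        inputs=data[:, :d],
        outputs=outputs,
        apd90_beat19=data[:, d + len(out_names)],
        seed=meta.get("seed"),
        failures=[tuple(f) for f in meta.get("failures", [])],
    )


@dataclass
class RunConfig:
    """Serialisable description of a pipeline run (model, protocol, seeds)."""

    model: str = "beeler_reuter_1977"
    protocol: str = "single_ap"
    protocol_options: dict = field(default_factory=dict)
    noise_sd: float = 0.25
    prior_factors: tuple = (0.1, 10.0)
    n_iterations: int = 100_000
    n_prepace: int = 100
    seed: int = 1
    output_dir: str = "."

    def to_dict(self) -> dict:
        d = asdict(self)
        d["prior_factors"] = list(d["prior_factors"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "prior_factors" in d:
            d["prior_factors"] = tuple(d["prior_factors"])
        return cls(**d)

    def save(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        """Stable short hash identifying this configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
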