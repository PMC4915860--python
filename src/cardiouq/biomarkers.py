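"""Action-potential shape descriptors extracted from a voltage trace.

Six per-beat biomarkers: maximum dVm/dt, maximum Vm, dome Vm, APD90,
resting Vm and APD50.

Conventions (applied identically to simulator output and emulator targets):

* resting Vm is the sample immediately before the beat's stimulus;
* the upstroke instant is the time of maximum central-difference dVm/dt
  (excluding the stimulus artifact window by default);
* APD_x is measured from the upstroke instant to the linearly interpolated
  downward crossing of V_peak - (x/100) (V_peak - V_rest);
* dome Vm is the maximum Vm between the post-spike notch (first local
  minimum after the peak) and 80% of APD90; without a notch, the plateau
  maximum from 30 ms after the upstroke.

A beat that never repolarises past a threshold leaves that APD undefined
(``None``); a flat window leaves all AP markers undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulation import VoltageTrace

__all__ = ["Biomarkers", "extract", "extract_beats", "BIOMARKER_NAMES"]

BIOMARKER_NAMES = ("max_dvdt", "max_vm", "dome_vm", "apd90", "resting_vm", "apd50")

#: Below this AP amplitude (mV) a window is considered non-excited.
MIN_AP_AMPLITUDE = 10.0


@dataclass(frozen=True)
class Biomarkers:
    max_dvdt: float | None  # mV/ms
    max_vm: float | None  # mV
    dome_vm: float | None  # mV
    apd90: float | None  # ms
    resting_vm: float  # mV
    apd50: float | None  # ms

    def as_dict(self) -> dict:
        return {n: getattr(self, n) for n in BIOMARKER_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array(
            [np.nan if getattr(self, n) is None else getattr(self, n) for n in BIOMARKER_NAMES]
        )


def _apd(times, v, i_peak, t_up, v_peak, v_rest, fraction):
    threshold = v_peak - fraction * (v_peak - v_rest)
    below = np.nonzero(v[i_peak:] < threshold)[0]
    if below.size == 0:
        return None
    k = i_peak + below[0]
    if k == 0:
        return None
    # linear interpolation between samples k-1 and k
    v0, v1 = v[k - 1], v[k]
    t_cross = times[k - 1] + (threshold - v0) / (v1 - v0) * (times[k] - times[k - 1])
    return float(t_cross - t_up)


def _smooth(v, half_width):
    if half_width < 1:
        return v
    w = 2 * half_width + 1
    kernel = np.ones(w) / w
    pad = np.concatenate((np.full(half_width, v[0]), v, np.full(half_width, v[-1])))
    return np.convolve(pad, kernel, mode="valid")


def extract(
    trace: VoltageTrace,
    beat_start: float | None = None,
    beat_period: float | None = None,
    exclude_stimulus_ms: float | None = None,
) -> Biomarkers:
    """Extract biomarkers of the single stimulated beat starting at
    ``beat_start`` (default: start of trace) lasting ``beat_period`` ms
    (default: to the end of the trace).

    ``exclude_stimulus_ms`` optionally removes an initial stimulus-artifact
    window from the max-dVm/dt search. The default includes all samples:
    under a current-clamp stimulus the sodium upstroke itself occurs inside
    the stimulus window, so excluding it would measure the plateau slope
    instead of the upstroke velocity. Excluding the window is useful for
    experimental recordings with a large electrode artifact.
    """
    if beat_start is None:
        beat_start = trace.start_time
    if beat_period is None:
        beat_period = trace.start_time + trace.duration - beat_start
    w = trace.window(beat_start, beat_period)
    v = w.voltages
    t = w.times
    dt = w.sample_interval

    resting = float(v[0])
    v_peak = float(np.max(v))
    i_peak = int(np.argmax(v))

    if v_peak - resting < MIN_AP_AMPLITUDE:
        return Biomarkers(None, None, None, None, resting, None)

    dvdt = np.gradient(v, dt)
    mask = np.ones(v.size, dtype=bool)
    if exclude_stimulus_ms is not None:
        mask &= t > beat_start + exclude_stimulus_ms + 1e-9
    # restrict the upstroke search to before (and including) the peak
    mask[i_peak + 1 :] = False
    if not mask.any():
        mask = np.ones(v.size, dtype=bool)
    i_up = int(np.nonzero(mask)[0][np.argmax(dvdt[mask])])
    max_dvdt = float(dvdt[i_up])
    t_up = t[i_up]

    apd90 = _apd(t, v, i_peak, t_up, v_peak, resting, 0.90)
    apd50 = _apd(t, v, i_peak, t_up, v_peak, resting, 0.50)

    # dome: first local minimum (notch) after the spike, on a ~1 ms smoothed copy
    dome = None
    half = max(int(round(0.5 / dt)), 1)
    vs = _smooth(v, half)
    end_idx = v.size - 1
    if apd90 is not None:
        end_idx = min(end_idx, i_up + int(round(0.8 * apd90 / dt)))
    notch = None
    for i in range(i_peak + 1, end_idx):
        if vs[i] < vs[i - 1] - 1e-12 and vs[i] <= vs[i + 1] + 1e-12:
            # require it to be an actual dip, not the tail of repolarisation
            rest_of = vs[i : end_idx + 1]
            if rest_of.size > 1 and np.max(rest_of) > vs[i] + 0.5:
                notch = i
                break
    if notch is not None:
        dome = float(np.max(v[notch : end_idx + 1]))
    else:
        i30 = i_up + int(round(30.0 / dt))
        if i30 < end_idx:
            dome = float(np.max(v[i30 : end_idx + 1]))

    return Biomarkers(max_dvdt, float(v_peak), dome, apd90, resting, apd50)


def extract_beats(trace: VoltageTrace, period: float, n_beats: int, **kwargs) -> list[Biomarkers]:
    """Per-beat biomarkers for a train of ``n_beats`` beats of ``period`` ms."""
    return [extract(trace, beat_start=k * period, beat_period=period, **kwargs) for k in range(n_beats)]


def write_biomarker_table(beats: list[Biomarkers], path) -> None:
    """Write a delimited text table, one row per beat (undefined -> nan)."""
    with open(path, "w") as fh:
        fh.write("beat\t" + "\t".join(BIOMARKER_NAMES) + "\n")
        for k, b in enumerate(beats, start=1):
            vals = "\t".join(f"{v:.6g}" for v in b.as_array())
            fh.write(f"{k}\t{vals}\n")
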