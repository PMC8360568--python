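"""Biomarker panel of a paced beat: AP and Ca2+-transient summary statistics.

The panel comprises, from the voltage trace: the resting membrane potential
(RMP, at stimulus onset), the AP amplitude (APA, peak minus RMP), the
maximal upstroke velocity (dvdt_max) and the AP durations APD10 ... APD90
(time from the instant of dvdt_max until the voltage has recovered the
given percentage of APA).  From the cytosolic Ca2+ transient, analogously:
resting level (CaR), amplitude (CaA), maximal upstroke velocity (dcdt_max)
and the transient durations CaD30, CaD50 and CaD80.

Conventions (stated because figure-style definitions leave them open):

* durations start at the instant of maximal upstroke velocity;
* repolarisation thresholds are percentages of the amplitude, not absolute
  voltages;
* ``CaDp`` defaults to "p% decay from the peak" (mirroring APDp); the
  alternative reading "width at p% of the amplitude above rest" is
  available via ``cad_convention="width"``;
* slopes come from central differences on the recorded grid, with the
  search starting at stimulus end to exclude the stimulus artifact;
* a threshold never re-crossed within the beat yields the beat-end value
  and the biomarker name is flagged in ``censored``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np

from .ap_model import Trace

__all__ = [
    "APD_PERCENTS",
    "CAD_PERCENTS",
    "BIOMARKER_NAMES",
    "BiomarkerSet",
    "NoActionPotentialError",
    "compute_biomarkers",
    "synth_trace",
]

APD_PERCENTS = (10, 20, 30, 40, 50, 60, 70, 80, 90)
CAD_PERCENTS = (30, 50, 80)

BIOMARKER_NAMES = (
    ("RMP", "APA", "dvdt_max")
    + tuple(f"APD{p}" for p in APD_PERCENTS)
    + ("CaR", "CaA", "dcdt_max")
    + tuple(f"CaD{p}" for p in CAD_PERCENTS)
)

#: Minimum voltage excursion (mV) that counts as a depolarisation.
_AP_DETECTION_RANGE = 20.0


class NoActionPotentialError(ValueError):
    """The trace contains no depolarisation to analyse."""


@dataclass(frozen=True)
class BiomarkerSet:
    """Values of the full biomarker panel for one beat.

    ``values`` maps each name in :data:`BIOMARKER_NAMES` to its value
    (mV, mV/ms, ms, uM or uM/ms as appropriate); ``censored`` lists
    duration biomarkers whose threshold was not re-crossed within the beat.
    """

    values: Mapping[str, float]
    censored: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        missing = set(BIOMARKER_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"missing biomarkers: {sorted(missing)}")
        object.__setattr__(self, "values", dict(self.values))
        object.__setattr__(self, "censored", frozenset(self.censored))

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __iter__(self) -> Iterator[str]:
        return iter(BIOMARKER_NAMES)

    def as_dict(self) -> dict[str, float]:
        return {n: self.values[n] for n in BIOMARKER_NAMES}

    def to_frame(self):
        """One row per biomarker: value, units, censored flag."""
        import pandas as pd

        units = {"RMP": "mV", "APA": "mV", "dvdt_max": "mV/ms",
                 "CaR": "uM", "CaA": "uM", "dcdt_max": "uM/ms"}
        rows = [
            (n, self.values[n], units.get(n, "ms"), n in self.censored)
            for n in BIOMARKER_NAMES
        ]
        return pd.DataFrame(rows, columns=["biomarker", "value", "units", "censored"])


def _cross_down(t: np.ndarray, x: np.ndarray, start: int, level: float):
    """First downward crossing of ``level`` at or after index ``start``,
    linearly interpolated; None if never re-crossed."""
    above = x[start:] >= level
    below = ~above[1:] & above[:-1]
    idx = np.nonzero(below)[0]
    if idx.size == 0:
        return None
    i = start + idx[0]
    x0, x1 = x[i], x[i + 1]
    frac = (x0 - level) / (x0 - x1) if x1 != x0 else 0.0
    return t[i] + frac * (t[i + 1] - t[i])


def _cross_up(t: np.ndarray, x: np.ndarray, stop: int, level: float):
    """Last upward crossing of ``level`` at or before index ``stop``."""
    seg = x[: stop + 1]
    below = seg[:-1] <= level
    above = seg[1:] > level
    idx = np.nonzero(below & above)[0]
    if idx.size == 0:
        return None
    i = idx[-1]
    x0, x1 = x[i], x[i + 1]
    frac = (level - x0) / (x1 - x0) if x1 != x0 else 0.0
    return t[i] + frac * (t[i + 1] - t[i])


def _upstroke(t, x, start_idx, peak_idx):
    """Index and value of the maximal central-difference slope on
    [start_idx, peak_idx]."""
    dxdt = np.gradient(x, t)
    stop = max(peak_idx, start_idx + 1)
    window = dxdt[start_idx : stop + 1]
    k = start_idx + int(np.argmax(window))
    return k, float(dxdt[k])


def compute_biomarkers(trace: Trace, cad_convention: str = "decay") -> BiomarkerSet:
    """Extract the full biomarker panel from one paced beat.

    Raises :class:`NoActionPotentialError` when the voltage excursion is
    below 20 mV.  Censored durations take the beat-end value and are listed
    in ``BiomarkerSet.censored``.
    """
    if cad_convention not in ("decay", "width"):
        raise ValueError("cad_convention must be 'decay' or 'width'")
    t, v, ca = trace.time, trace.v, trace.ca
    if v.max() - v.min() <= _AP_DETECTION_RANGE:
        raise NoActionPotentialError(
            f"no AP detected: voltage range {v.max() - v.min():.2f} mV <= "
            f"{_AP_DETECTION_RANGE} mV"
        )
    # first index at/after stimulus end: excludes the stimulus artifact
    start = int(np.searchsorted(t, trace.stimulus_duration))
    values: dict[str, float] = {}
    censored: set[str] = set()

    rmp = float(v[0])
    peak_idx = int(np.argmax(v))
    peak = float(v[peak_idx])
    apa = peak - rmp
    up_idx, dvdt_max = _upstroke(t, v, start, peak_idx)
    t_up = float(t[up_idx])
    values.update(RMP=rmp, APA=apa, dvdt_max=dvdt_max)
    for p in APD_PERCENTS:
        level = peak - apa * p / 100.0
        tc = _cross_down(t, v, peak_idx, level)
        name = f"APD{p}"
        if tc is None:
            censored.add(name)
            tc = float(t[-1])
        values[name] = tc - t_up

    ca_r = float(ca[0])
    ca_peak_idx = int(np.argmax(ca))
    ca_peak = float(ca[ca_peak_idx])
    ca_a = ca_peak - ca_r
    ca_up_idx, dcdt_max = _upstroke(t, ca, start, ca_peak_idx)
    t_ca_up = float(t[ca_up_idx])
    values.update(CaR=ca_r, CaA=ca_a, dcdt_max=dcdt_max)
    for p in CAD_PERCENTS:
        name = f"CaD{p}"
        if cad_convention == "decay":
            level = ca_peak - ca_a * p / 100.0
            tc = _cross_down(t, ca, ca_peak_idx, level)
            if tc is None:
                censored.add(name)
                tc = float(t[-1])
            values[name] = tc - t_ca_up
        else:  # width at p% of amplitude above rest
            level = ca_r + ca_a * p / 100.0
            t_dn = _cross_down(t, ca, ca_peak_idx, level)
            if t_dn is None:
                censored.add(name)
                t_dn = float(t[-1])
            t_upcross = _cross_up(t, ca, ca_peak_idx, level)
            values[name] = t_dn - (t_upcross if t_upcross is not None else t_ca_up)
    return BiomarkerSet(values=values, censored=frozenset(censored))


# ---------------------------------------------------------------------------
# synthetic traces with closed-form biomarkers (test fixtures)
# ---------------------------------------------------------------------------


def _rise(t, t0, ramp, rest, amp):
    """Quadratic ease-in from rest to rest+amp over [t0, t0+ramp].

    The slope grows linearly, so the maximal upstroke velocity
    (2*amp/ramp) is attained at the end of the ramp, i.e. at the peak —
    which makes the duration start-reference unambiguous."""
    x = np.full_like(t, rest, dtype=float)
    on = (t >= t0) & (t < t0 + ramp)
    x[on] = rest + amp * ((t[on] - t0) / ramp) ** 2
    x[t >= t0 + ramp] = rest + amp
    return x


def synth_trace(
    v_rest: float = -80.0,
    v_amp: float = 120.0,
    v_ramp: float = 2.0,
    v_decay: float = 300.0,
    v_decay_law: str = "linear",
    ca_rest: float = 0.1,
    ca_amp: float = 0.5,
    ca_ramp: float = 20.0,
    ca_tau: float = 150.0,
    ca_decay_law: str = "exp",
    beat_length: float = 1000.0,
    dt: float = 0.05,
) -> tuple[Trace, BiomarkerSet]:
    """Build a synthetic beat whose biomarkers are known in closed form.

    The upstroke is a quadratic ease-in (maximal slope ``2*amp/ramp`` at the
    peak); decay is linear over ``v_decay`` ms or exponential with time
    constant ``ca_tau``.  Returns the trace together with its analytic
    :class:`BiomarkerSet` (durations referenced to the peak, where the
    maximal slope occurs).
    """
    if v_amp <= 0 or ca_amp <= 0:
        raise ValueError("amplitudes must be positive")
    if min(v_ramp, v_decay, ca_ramp, ca_tau, beat_length, dt) <= 0:
        raise ValueError("time parameters must be positive")
    if v_ramp + v_decay >= beat_length or ca_ramp >= beat_length:
        raise ValueError("waveform does not fit in the beat")
    if v_decay_law not in ("linear", "exp") or ca_decay_law not in ("linear", "exp"):
        raise ValueError("decay law must be 'linear' or 'exp'")

    t = np.arange(0.0, beat_length + dt / 2, dt)
    values: dict[str, float] = {}
    censored: set[str] = set()

    def waveform(rest, amp, ramp, law, scale):
        x = _rise(t, 0.0, ramp, rest, amp)
        tail = t >= ramp
        s = t[tail] - ramp
        if law == "linear":
            x[tail] = np.maximum(rest + amp * (1.0 - s / scale), rest)
        else:
            x[tail] = rest + amp * np.exp(-s / scale)
        return x

    v = waveform(v_rest, v_amp, v_ramp, v_decay_law, v_decay)
    ca = waveform(ca_rest, ca_amp, ca_ramp, ca_decay_law, ca_tau)

    def durations(prefix, percents, amp, law, scale):
        for p in percents:
            if law == "linear":
                d = scale * p / 100.0
            else:
                d = -scale * math.log(1.0 - p / 100.0)
            if d > beat_length - (v_ramp if prefix == "APD" else ca_ramp):
                censored.add(f"{prefix}{p}")
            values[f"{prefix}{p}"] = d

    values.update(
        RMP=v_rest, APA=v_amp, dvdt_max=2.0 * v_amp / v_ramp,
        CaR=ca_rest, CaA=ca_amp, dcdt_max=2.0 * ca_amp / ca_ramp,
    )
    durations("APD", APD_PERCENTS, v_amp, v_decay_law, v_decay)
    durations("CaD", CAD_PERCENTS, ca_amp, ca_decay_law, ca_tau)

    trace = Trace(time=t, v=v, ca=ca, cycle_length=beat_length,
                  stimulus_duration=0.0)
    return trace, BiomarkerSet(values=values, censored=frozenset(censored))
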