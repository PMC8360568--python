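"""Single-cell action-potential / Ca2+ model with a density-flux current split.

Every membrane current is factorised as ``I_i = rho_i * J_i`` where ``rho_i``
is a dimensionless channel-density scaling (the number of channels per unit
membrane capacitance, folded into one factor) and ``J_i`` is the
per-channel flux ``g0 * o * (v - E)``.  The split carries the two central
modelling assumptions:

* maturation / species translation (hiPSC-CM <-> rabbit <-> adult human)
  changes only ``rho_i``;
* a channel mutation changes only ``J_i`` (here: the SQT1 mutation N588K,
  a gain of function of I_Kr represented as a +62 mV shift and 1.85x slope
  scaling of the inactivation-gate steady state);
* a drug scales ``J_i`` by a per-current factor, so drug factors commute
  with cell-type translation.

The concrete parameterisation shipped in ``data/surrogate_model.yaml`` is a
surrogate ventricular model: Hodgkin-Huxley-style gates and a phenomeno-
logical cytosolic Ca2+ subsystem, built to reproduce the qualitative SQT1
phenotype (shorter APD, depressed Ca2+ transient) rather than any published
cell line.  The loader accepts any parameter set following the same schema.

Voltages are mV, time is ms, currents are A/F, cytosolic Ca2+ is uM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from numba import njit

__all__ = [
    "CELL_TYPES",
    "MUTATIONS",
    "CURRENT_IDS",
    "GATE_IDS",
    "STATE_NAMES",
    "CurrentSpec",
    "GateModel",
    "APModel",
    "PacingProtocol",
    "Trace",
    "SimulationError",
    "xkr2_inf",
    "build_model",
    "default_model_path",
    "simulate",
    "simulate_reference",
    "pace_to_steady",
    "translate_cell_type",
    "diastolic_threshold",
]

CELL_TYPES = ("hiPSC-CM", "rabbit", "adult-human")
MUTATIONS = ("WT", "N588K")

# Fixed current set of the surrogate model (order matters for packing).
CURRENT_IDS = ("I_Na", "I_NaL", "I_CaL", "I_Kr", "I_Ks", "I_K1", "I_f", "I_b")
GATE_IDS = ("m", "h", "d", "f", "xr1", "xs", "y", "mL")
STATE_NAMES = ("v", "m", "h", "d", "f", "xr1", "xs", "y", "mL", "cai")

_N_CUR = len(CURRENT_IDS)
_N_GATES = len(GATE_IDS)

# --- packed parameter vector layout -----------------------------------------
_PG0 = 0                      # 8: effective conductance g0 * rho per current
_PREV = _PG0 + _N_CUR         # 5: reversal potentials E_Na, E_K, E_Ca, E_f, E_b
_PXKR2 = _PREV + 5            # 2: I_Kr inactivation steady state: v_half, slope
_PK1 = _PXKR2 + 2             # 2: I_K1 instantaneous rectification: v_half, slope
_PCA = _PK1 + 2               # 3: ca_rest, tau_decay, release_gain
_PGATE = _PCA + 3             # 8 gates x 7 params: v_half, slope, floor,
_GATE_NP = 7                  #                     tau_base, tau_amp, tau_vc, tau_sigma
_NPARAMS = _PGATE + _N_GATES * _GATE_NP

# WT inactivation-gate steady state of I_Kr: 1 / (1 + exp((v + 70) / 20.9)).
_XKR2_WT = (-70.0, 20.9)
# N588K: midpoint shifted by +62 mV, slope scaled by 1.85.
_XKR2_N588K = (-70.0 + 62.0, 20.9 * 1.85)


def xkr2_inf(v, variant: str = "WT"):
    """Steady state of the I_Kr inactivation gate x_Kr2.

    ``variant`` selects the wild-type curve (midpoint -70 mV, slope
    20.9 mV) or the N588K gain-of-function curve (midpoint shifted +62 mV,
    slope widened 1.85x).  Accepts scalars or arrays; values lie in (0, 1)
    and decrease with depolarisation (inward rectification of hERG).
    """
    arr = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("membrane potential must be finite")
    if variant == "WT":
        vh, s = _XKR2_WT
    elif variant == "N588K":
        vh, s = _XKR2_N588K
    else:
        raise ValueError(f"unknown variant {variant!r}; expected one of {MUTATIONS}")
    out = 1.0 / (1.0 + np.exp((arr - vh) / s))
    return float(out) if np.isscalar(v) else out


class SimulationError(RuntimeError):
    """Integrator failure; carries the time (ms into the run) of the blow-up."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


@dataclass(frozen=True)
class GateModel:
    """One Hodgkin-Huxley gate: Boltzmann steady state and Gaussian-bell tau.

    ``steady_state(v) = floor + (1 - floor) / (1 + exp(-(v - v_half)/slope))``
    (a negative slope encodes an inactivation gate) and
    ``time_constant(v) = tau_base + tau_amp * exp(-((v - tau_vc)/tau_sigma)^2)``.
    """

    v_half: float
    slope: float
    floor: float = 0.0
    tau_base: float = 1.0
    tau_amp: float = 0.0
    tau_vc: float = 0.0
    tau_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("gate slope must be nonzero")
        if not 0.0 <= self.floor < 1.0:
            raise ValueError("gate floor must lie in [0, 1)")
        if self.tau_base <= 0 or self.tau_amp < 0 or self.tau_sigma <= 0:
            raise ValueError("gate time-constant parameters must be positive")

    def steady_state(self, v: float) -> float:
        return self.floor + (1.0 - self.floor) / (
            1.0 + math.exp(-(v - self.v_half) / self.slope)
        )

    def time_constant(self, v: float) -> float:
        z = (v - self.tau_vc) / self.tau_sigma
        return self.tau_base + self.tau_amp * math.exp(-z * z)


@dataclass(frozen=True)
class CurrentSpec:
    """One membrane current: density scaling ``rho`` and flux parameters.

    ``flux_params`` holds the single-channel conductance ``g0`` (A/F per mV
    at rho = 1) and the name of the reversal potential; the gate wiring is
    fixed per ``current_id`` (see the integrator kernel).
    """

    current_id: str
    rho: float
    flux_params: Mapping[str, float | str]

    def __post_init__(self) -> None:
        if self.current_id not in CURRENT_IDS:
            raise ValueError(f"unknown current_id {self.current_id!r}")
        if self.rho < 0:
            raise ValueError(f"rho must be nonnegative, got {self.rho}")
        object.__setattr__(self, "flux_params", dict(self.flux_params))


@dataclass(frozen=True)
class PacingProtocol:
    """Regular pacing with a rectangular stimulus current.

    ``n_prebeats`` is the maximum number of conditioning beats; pacing stops
    earlier once every biomarker changes by less than ``steady_tolerance``
    (relative) between consecutive beats.  ``dt`` is the fixed integration
    step; the trace is recorded every ``record_stride`` steps (default
    0.025 ms x 2 = 0.05 ms grid).
    """

    cycle_length: float = 1000.0
    stimulus_amplitude: float = 60.0
    stimulus_duration: float = 1.0
    n_prebeats: int = 100
    steady_tolerance: float = 1e-3
    dt: float = 0.025
    record_stride: int = 2

    def __post_init__(self) -> None:
        if not self.cycle_length > self.stimulus_duration > 0:
            raise ValueError("need cycle_length > stimulus_duration > 0")
        if self.n_prebeats < 1:
            raise ValueError("n_prebeats must be >= 1")
        if self.dt <= 0 or self.record_stride < 1:
            raise ValueError("dt must be positive and record_stride >= 1")


@dataclass(frozen=True)
class Trace:
    """One paced beat: time grid (ms from stimulus onset), v (mV), cytosolic
    Ca2+ (uM) and optional per-current series (A/F)."""

    time: np.ndarray
    v: np.ndarray
    ca: np.ndarray
    currents: Mapping[str, np.ndarray] | None = None
    cycle_length: float = 1000.0
    stimulus_duration: float = 1.0

    def __post_init__(self) -> None:
        if len(self.time) != len(self.v) or len(self.time) != len(self.ca):
            raise ValueError("time, v and ca must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not (np.all(np.isfinite(self.v)) and np.all(np.isfinite(self.ca))):
            raise ValueError("v and ca must be finite everywhere")

    def to_frame(self):
        """Export as a DataFrame (columns time_ms, v_mV, ca_uM, currents)."""
        import pandas as pd

        data = {"time_ms": self.time, "v_mV": self.v, "ca_uM": self.ca}
        if self.currents:
            for cid, arr in self.currents.items():
                data[cid] = arr
        return pd.DataFrame(data)


@dataclass(frozen=True)
class APModel:
    """A fully specified cell model: currents, gates, cell type and mutation.

    Construct through :func:`build_model`; ``translate_cell_type`` and
    ``with_mutation`` derive variants that respect the rho/J orthogonality.
    """

    name: str
    currents: Mapping[str, CurrentSpec]
    gates: Mapping[str, GateModel]
    cell_type: str
    mutation: str
    config: dict = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {self.cell_type!r}")
        if self.mutation not in MUTATIONS:
            raise ValueError(f"unknown mutation {self.mutation!r}")
        object.__setattr__(self, "currents", dict(self.currents))
        object.__setattr__(self, "gates", dict(self.gates))

    # -- packing -------------------------------------------------------------
    def packed_params(self) -> np.ndarray:
        P = np.zeros(_NPARAMS)
        rev = self.config["reversal"]
        for i, cid in enumerate(CURRENT_IDS):
            spec = self.currents[cid]
            P[_PG0 + i] = float(spec.flux_params["g0"]) * spec.rho
        P[_PREV : _PREV + 5] = [
            rev["E_Na"], rev["E_K"], rev["E_Ca"], rev["E_f"], rev["E_b"]
        ]
        vh, s = _XKR2_WT if self.mutation == "WT" else _XKR2_N588K
        P[_PXKR2], P[_PXKR2 + 1] = vh, s
        k1 = self.config["k1_rectification"]
        P[_PK1], P[_PK1 + 1] = k1["v_half"], k1["slope"]
        ca = self.config["calcium"]
        P[_PCA : _PCA + 3] = [ca["ca_rest"], ca["tau_decay"], ca["release_gain"]]
        for gi, gid in enumerate(GATE_IDS):
            g = self.gates[gid]
            base = _PGATE + gi * _GATE_NP
            P[base : base + _GATE_NP] = [
                g.v_half, g.slope, g.floor,
                g.tau_base, g.tau_amp, g.tau_vc, g.tau_sigma,
            ]
        return P

    def resting_state(self) -> np.ndarray:
        """Initial state: configured v and cai, gates at steady state."""
        init = self.config.get("initial_state", {})
        v0 = float(init.get("v", -85.0))
        cai0 = float(init.get("cai", self.config["calcium"]["ca_rest"]))
        y = np.empty(len(STATE_NAMES))
        y[0] = v0
        for gi, gid in enumerate(GATE_IDS):
            y[1 + gi] = self.gates[gid].steady_state(v0)
        y[-1] = cai0
        return y

    def state_dict(self, y: np.ndarray) -> dict[str, float]:
        return dict(zip(STATE_NAMES, np.asarray(y, dtype=float)))

    # -- per-current evaluation (used by tests and reports) -------------------
    def current_values(
        self, state: Mapping[str, float] | np.ndarray,
        factors: Mapping[str, float] | None = None,
    ) -> dict[str, float]:
        """Evaluate every membrane current at a fixed state vector."""
        y = self._as_state_array(state)
        fac = _factor_array(factors)
        vals = _currents(y, self.packed_params(), fac)
        return dict(zip(CURRENT_IDS, map(float, vals)))

    def _as_state_array(self, state) -> np.ndarray:
        if isinstance(state, Mapping):
            return np.array([state[n] for n in STATE_NAMES], dtype=float)
        y = np.asarray(state, dtype=float)
        if y.shape != (len(STATE_NAMES),):
            raise ValueError(f"state must have {len(STATE_NAMES)} entries")
        return y

    def with_mutation(self, mutation: str) -> "APModel":
        """Same cell, other genotype: only the I_Kr gate variant changes."""
        if mutation not in MUTATIONS:
            raise ValueError(f"unknown mutation {mutation!r}")
        return replace(self, mutation=mutation)


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

_REQUIRED_TOP_KEYS = ("currents", "gates", "reversal", "calcium", "k1_rectification")


def build_model(
    source: str | Path | Mapping, cell_type: str, mutation: str = "WT"
) -> APModel:
    """Build an :class:`APModel` from a YAML parameter file or parsed dict.

    Every current block must provide ``g0`` and a ``rho`` entry for the
    requested ``cell_type``; unknown current ids and missing rho values are
    schema errors.
    """
    if isinstance(source, Mapping):
        cfg = dict(source)
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    for key in _REQUIRED_TOP_KEYS:
        if key not in cfg:
            raise ValueError(f"model config missing section {key!r}")
    if cell_type not in CELL_TYPES:
        raise ValueError(f"unknown cell type {cell_type!r}; expected {CELL_TYPES}")

    currents: dict[str, CurrentSpec] = {}
    for cid, block in cfg["currents"].items():
        if cid not in CURRENT_IDS:
            raise ValueError(f"unknown current_id {cid!r} in model config")
        rho_profile = block.get("rho", {})
        if cell_type not in rho_profile:
            raise ValueError(f"current {cid!r} has no rho for cell type {cell_type!r}")
        currents[cid] = CurrentSpec(
            current_id=cid,
            rho=float(rho_profile[cell_type]),
            flux_params={"g0": float(block["g0"]), "reversal": block.get("reversal", "")},
        )
    missing = set(CURRENT_IDS) - set(currents)
    if missing:
        raise ValueError(f"model config missing currents: {sorted(missing)}")

    gates = {gid: GateModel(**cfg["gates"][gid]) for gid in GATE_IDS}
    return APModel(
        name=str(cfg.get("name", "model")),
        currents=currents,
        gates=gates,
        cell_type=cell_type,
        mutation=mutation,
        config=cfg,
    )


def default_model_path() -> Path:
    """Path of the surrogate ventricular parameter set shipped with the package."""
    return Path(__file__).parent / "data" / "surrogate_model.yaml"


def translate_cell_type(model: APModel, target: str) -> APModel:
    """Re-parameterise for another cell type: only rho values change.

    Flux parameters, gate kinetics and the mutation flag are untouched, so
    per-channel drug factors carry over unchanged.
    """
    if target not in CELL_TYPES:
        raise ValueError(f"unknown cell type {target!r}; expected {CELL_TYPES}")
    if target == model.cell_type:
        return model
    return build_model(model.config, target, model.mutation)


# ---------------------------------------------------------------------------
# integration kernel (fixed-step exponential / Rush-Larsen scheme)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _currents(y, P, fac):
    """All membrane currents (A/F) at state ``y``; ``fac`` scales each J."""
    v = y[0]
    m, h, d, f, xr1, xs, yf, mL = y[1], y[2], y[3], y[4], y[5], y[6], y[7], y[8]
    e_na, e_k, e_ca, e_f, e_b = P[_PREV], P[_PREV + 1], P[_PREV + 2], P[_PREV + 3], P[_PREV + 4]
    out = np.empty(_N_CUR)
    # I_Na: fast inward sodium, m^3 h
    out[0] = fac[0] * P[_PG0 + 0] * m * m * m * h * (v - e_na)
    # I_NaL: late (slowly inactivating) sodium
    out[1] = fac[1] * P[_PG0 + 1] * mL * (v - e_na)
    # I_CaL: L-type calcium (ohmic driving-force approximation)
    out[2] = fac[2] * P[_PG0 + 2] * d * f * (v - e_ca)
    # I_Kr: rapid delayed rectifier; inactivation gate is instantaneous
    xkr2 = 1.0 / (1.0 + math.exp((v - P[_PXKR2]) / P[_PXKR2 + 1]))
    out[3] = fac[3] * P[_PG0 + 3] * xr1 * xkr2 * (v - e_k)
    # I_Ks: slow delayed rectifier
    out[4] = fac[4] * P[_PG0 + 4] * xs * (v - e_k)
    # I_K1: inward rectifier with instantaneous rectification
    r_inf = 1.0 / (1.0 + math.exp((v - P[_PK1]) / P[_PK1 + 1]))
    out[5] = fac[5] * P[_PG0 + 5] * r_inf * (v - e_k)
    # I_f: funny (hyperpolarisation-activated) current
    out[6] = fac[6] * P[_PG0 + 6] * yf * (v - e_f)
    # I_b: linear background current
    out[7] = fac[7] * P[_PG0 + 7] * (v - e_b)
    return out


@njit(cache=True)
def _gate_targets(v, P):
    """Steady states and time constants of all gates at voltage ``v``."""
    ss = np.empty(_N_GATES)
    tau = np.empty(_N_GATES)
    for gi in range(_N_GATES):
        base = _PGATE + gi * _GATE_NP
        vh, s, floor = P[base], P[base + 1], P[base + 2]
        tb, ta, tvc, tsig = P[base + 3], P[base + 4], P[base + 5], P[base + 6]
        ss[gi] = floor + (1.0 - floor) / (1.0 + math.exp(-(v - vh) / s))
        z = (v - tvc) / tsig
        tau[gi] = tb + ta * math.exp(-z * z)
    return ss, tau


@njit(cache=True)
def _ca_flux(y, P, fac):
    """Cytosolic Ca2+ flux: release driven by the open fraction of the
    L-type channel (at a fixed 60 mV effective driving force, so that the
    open *time* rather than the instantaneous ohmic driving force sets the
    transient amplitude), minus first-order removal toward the resting
    level."""
    ca_rest, tau_ca, gain = P[_PCA], P[_PCA + 1], P[_PCA + 2]
    release = gain * fac[2] * P[_PG0 + 2] * y[3] * y[4] * 60.0
    return release - (y[-1] - ca_rest) / tau_ca


@njit(cache=True)
def _rhs(y, P, fac, istim):
    """Time derivative of the full state (used by the reference integrator)."""
    cur = _currents(y, P, fac)
    dy = np.empty(y.shape[0])
    total = 0.0
    for i in range(_N_CUR):
        total += cur[i]
    dy[0] = -total + istim
    ss, tau = _gate_targets(y[0], P)
    for gi in range(_N_GATES):
        dy[1 + gi] = (ss[gi] - y[1 + gi]) / tau[gi]
    dy[-1] = _ca_flux(y, P, fac)
    return dy


@njit(cache=True)
def _run_beat(y, P, fac, dt, n_steps, stim_amp, stim_dur, stride, record):
    """Advance one cycle in place; optionally record v, ca and currents.

    Gates use exponential (Rush-Larsen) updates, v and Ca2+ forward Euler.
    Returns (status, t_fail, v_rec, ca_rec, cur_rec); status 1 flags a
    non-finite state (step-size collapse equivalent for this scheme).
    """
    n_rec = n_steps // stride + 1 if record else 1
    v_rec = np.empty(n_rec)
    ca_rec = np.empty(n_rec)
    cur_rec = np.empty((n_rec, _N_CUR))
    k = 0
    for step in range(n_steps + 1):
        t = step * dt
        cur = _currents(y, P, fac)
        if record and step % stride == 0:
            v_rec[k] = y[0]
            ca_rec[k] = y[-1]
            for i in range(_N_CUR):
                cur_rec[k, i] = cur[i]
            k += 1
        if step == n_steps:
            break
        total = 0.0
        for i in range(_N_CUR):
            total += cur[i]
        istim = stim_amp if t < stim_dur else 0.0
        v_new = y[0] + dt * (-total + istim)
        ca_new = y[-1] + dt * _ca_flux(y, P, fac)
        if ca_new < 1e-6:
            ca_new = 1e-6
        ss, tau = _gate_targets(y[0], P)
        for gi in range(_N_GATES):
            x = y[1 + gi]
            y[1 + gi] = ss[gi] + (x - ss[gi]) * math.exp(-dt / tau[gi])
        y[0] = v_new
        y[-1] = ca_new
        if not (math.isfinite(v_new) and math.isfinite(ca_new)):
            return 1, t, v_rec, ca_rec, cur_rec
    return 0, 0.0, v_rec, ca_rec, cur_rec


def _factor_array(factors: Mapping[str, float] | None) -> np.ndarray:
    fac = np.ones(_N_CUR)
    if factors:
        for cid, f in factors.items():
            if cid not in CURRENT_IDS:
                # Currents absent from this model contribute factor 1; a
                # warning (not an error) lets one drug library serve
                # several models.
                import warnings

                warnings.warn(f"factor for current {cid!r} not in model; ignored")
                continue
            if f < 0:
                raise ValueError(f"factor for {cid!r} must be nonnegative, got {f}")
            fac[CURRENT_IDS.index(cid)] = f
    return fac


def _beat_steps(protocol: PacingProtocol) -> int:
    n = int(round(protocol.cycle_length / protocol.dt))
    # keep the recording grid aligned with the beat
    return (n // protocol.record_stride) * protocol.record_stride


def _beat_biomarker_vector(v_rec, ca_rec):
    """Cheap per-beat summary used only for the steady-pacing check."""
    return np.array(
        [v_rec[0], v_rec.max(), v_rec.min(), np.trapezoid(v_rec),
         ca_rec[0], ca_rec.max(), np.trapezoid(ca_rec)]
    )


def pace_to_steady(
    model: APModel,
    protocol: PacingProtocol | None = None,
    factors: Mapping[str, float] | None = None,
    initial_state: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Pace until consecutive beats agree to ``steady_tolerance`` (relative).

    Returns the state at the start of the next beat and the number of beats
    integrated (at most ``n_prebeats``).
    """
    protocol = protocol or PacingProtocol()
    P = model.packed_params()
    fac = _factor_array(factors)
    y = (model.resting_state() if initial_state is None
         else np.array(initial_state, dtype=float))
    n_steps = _beat_steps(protocol)
    prev = None
    for beat in range(1, protocol.n_prebeats + 1):
        status, t_fail, v_rec, ca_rec, _ = _run_beat(
            y, P, fac, protocol.dt, n_steps,
            protocol.stimulus_amplitude, protocol.stimulus_duration,
            protocol.record_stride, True,
        )
        if status != 0:
            raise SimulationError(
                f"integration diverged at t = {t_fail:.3f} ms of beat {beat}",
                t_fail=t_fail,
            )
        summary = _beat_biomarker_vector(v_rec, ca_rec)
        if prev is not None:
            rel = np.abs(summary - prev) / np.maximum(np.abs(prev), 1e-9)
            if np.max(rel) < protocol.steady_tolerance:
                return y, beat
        prev = summary
    return y, protocol.n_prebeats


def simulate(
    model: APModel,
    protocol: PacingProtocol | None = None,
    factors: Mapping[str, float] | None = None,
    initial_state: np.ndarray | None = None,
    record_currents: bool = False,
) -> Trace:
    """Pace the model and return the final beat as a :class:`Trace`.

    ``factors`` maps current ids to nonnegative per-current scale factors
    (the multiplicative drug model); with all factors equal to 1 (or absent)
    this is exactly the drug-free model — the same code path is taken.
    """
    protocol = protocol or PacingProtocol()
    state, _ = pace_to_steady(model, protocol, factors, initial_state)
    P = model.packed_params()
    fac = _factor_array(factors)
    n_steps = _beat_steps(protocol)
    y = state.copy()
    status, t_fail, v_rec, ca_rec, cur_rec = _run_beat(
        y, P, fac, protocol.dt, n_steps,
        protocol.stimulus_amplitude, protocol.stimulus_duration,
        protocol.record_stride, True,
    )
    if status != 0:
        raise SimulationError(
            f"integration diverged at t = {t_fail:.3f} ms of the recorded beat",
            t_fail=t_fail,
        )
    t = np.arange(len(v_rec)) * protocol.dt * protocol.record_stride
    currents = None
    if record_currents:
        currents = {cid: cur_rec[:, i].copy() for i, cid in enumerate(CURRENT_IDS)}
    return Trace(
        time=t, v=v_rec, ca=ca_rec, currents=currents,
        cycle_length=protocol.cycle_length,
        stimulus_duration=protocol.stimulus_duration,
    )


def simulate_reference(
    model: APModel,
    protocol: PacingProtocol | None = None,
    factors: Mapping[str, float] | None = None,
    initial_state: np.ndarray | None = None,
    rtol: float = 1e-6,
) -> Trace:
    """One beat integrated with SciPy's adaptive stiff solver (LSODA).

    Slower than :func:`simulate` but independent of the fixed-step scheme;
    used as a numerical cross-check.  Starts from ``initial_state`` (or the
    paced steady state) and integrates a single cycle.
    """
    from scipy.integrate import solve_ivp

    protocol = protocol or PacingProtocol()
    if initial_state is None:
        initial_state, _ = pace_to_steady(model, protocol, factors)
    P = model.packed_params()
    fac = _factor_array(factors)
    amp, dur = protocol.stimulus_amplitude, protocol.stimulus_duration
    grid = np.arange(0.0, protocol.cycle_length + 1e-9,
                     protocol.dt * protocol.record_stride)

    def rhs(t, y):
        return _rhs(y, P, fac, amp if t < dur else 0.0)

    ts, ys = [], []
    y0 = np.array(initial_state, dtype=float)
    # split at the stimulus edge so LSODA never steps across the discontinuity
    for t0, t1 in ((0.0, dur), (dur, protocol.cycle_length)):
        t_eval = grid[(grid >= t0) & (grid <= t1)]
        if t_eval.size == 0 or t_eval[0] > t0:
            t_eval = np.concatenate(([t0], t_eval))
        if t_eval[-1] < t1:
            t_eval = np.concatenate((t_eval, [t1]))
        seg = solve_ivp(
            rhs, (t0, t1), y0, method="LSODA", rtol=rtol, atol=1e-9,
            t_eval=t_eval, max_step=5.0,
        )
        if not seg.success:
            raise SimulationError(f"reference solver failed: {seg.message}")
        y0 = seg.y[:, -1]
        keep = slice(None) if not ts else slice(1, None)  # drop duplicated edge
        ts.append(seg.t[keep])
        ys.append(seg.y[:, keep])
    t = np.concatenate(ts)
    y_all = np.concatenate(ys, axis=1)
    v = y_all[0]
    ca = y_all[-1]
    return Trace(
        time=t, v=v, ca=ca, currents=None,
        cycle_length=protocol.cycle_length,
        stimulus_duration=protocol.stimulus_duration,
    )


def diastolic_threshold(
    model: APModel,
    protocol: PacingProtocol | None = None,
    upper: float = 200.0,
    tol: float = 0.5,
) -> float:
    """Smallest 1-beat stimulus amplitude (A/F) that elicits an AP, by bisection.

    An AP counts as elicited when the voltage excursion within the beat
    exceeds 20 mV above its starting value plus the passive stimulus
    response.  Useful for setting the stimulus to a safety margin above
    threshold (e.g. 1.5x).
    """
    protocol = protocol or PacingProtocol()
    P = model.packed_params()
    fac = np.ones(_N_CUR)
    rest = model.resting_state()
    n_steps = _beat_steps(protocol)

    def fires(amp: float) -> bool:
        y = rest.copy()
        status, _, v_rec, _, _ = _run_beat(
            y, P, fac, protocol.dt, n_steps, amp,
            protocol.stimulus_duration, protocol.record_stride, True,
        )
        return status == 0 and v_rec.max() > rest[0] + 40.0

    lo, hi = 0.0, upper
    if not fires(hi):
        raise SimulationError(f"no AP elicited even at amplitude {upper} A/F")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return hi
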