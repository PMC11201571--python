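"""Single-neuron conductance-based membrane dynamics.

The membrane follows Hodgkin-Huxley kinetics with potassium (n^4), sodium
(m^3 h) and leak currents, plus a two-gate calcium channel (mCa^2 hCa) with
Boltzmann steady states and voltage-independent time constants.  Maximal K,
Na and Ca conductances may be scaled linearly from per-neuron gene
expression levels; capacitance and leak stay at the global constants.

Internal unit system: mV / ms / uF/cm^2 / mS/cm^2 / uA/cm^2.  Stimulus
amplitudes are quoted in nA at the interface with 1 nA == 1 uA/cm^2 by
default (configurable), which keeps interface numbers and current densities
interchangeable.

Two parameterizations matter:

* ``CELEGANS_CONSTANTS`` — the whole-brain network constants (Cm 3.1,
  gl 0.289, VK -75, VNa 55, Vl -84, VCa 45); K/Na/Ca conductances vary per
  neuron.
* ``classical_squid_params()`` — the textbook squid-axon parameterization
  used by the leak-conductance bifurcation scan, whose oscillation boundary
  sits near gl = 0.2994 mS/cm^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import _kernel
from .connectome import ChannelGeneMap, GeneExpressionTable

__all__ = [
    "NeuronParams",
    "MembraneState",
    "StimulusProtocol",
    "VoltageTrace",
    "ResponseClass",
    "CELEGANS_CONSTANTS",
    "classical_squid_params",
    "gating_rates",
    "steady_state_gates",
    "resting_state",
    "channel_currents",
    "conductances_from_expression",
    "simulate_neuron",
    "detect_spikes",
    "classify_response",
    "find_critical_leak",
    "find_threshold_amplitude",
    "IntegrationError",
]


class IntegrationError(RuntimeError):
    """Non-finite state encountered during integration."""

    def __init__(self, time_ms: float, neuron: object = None):
        self.time_ms = time_ms
        self.neuron = neuron
        where = f" in neuron {neuron!r}" if neuron is not None else ""
        super().__init__(f"integration blew up at t = {time_ms:.3f} ms{where}")


@dataclass(frozen=True)
class NeuronParams:
    """Channel densities (mS/cm^2), reversal potentials (mV) and calcium
    kinetics for one neuron."""

    Cm: float = 3.1        # uF/cm^2
    gK: float = 36.0
    gNa: float = 120.0
    gCa: float = 0.0
    gl: float = 0.289
    VK: float = -75.0
    VNa: float = 55.0
    Vl: float = -84.0
    VCa: float = 45.0
    # calcium gating: Boltzmann half-activation (mV), slope (mV), tau (ms)
    mca_half: float = -30.0
    mca_slope: float = 6.0
    mca_tau: float = 2.0
    hca_half: float = -50.0
    hca_slope: float = 6.0
    hca_tau: float = 40.0

    def __post_init__(self) -> None:
        if not self.Cm > 0:
            raise ValueError("Cm must be > 0")
        for name in ("gK", "gNa", "gCa", "gl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def as_row(self) -> np.ndarray:
        row = np.empty(_kernel.NPARAM)
        row[_kernel.CM] = self.Cm
        row[_kernel.GK] = self.gK
        row[_kernel.GNA] = self.gNa
        row[_kernel.GCA] = self.gCa
        row[_kernel.GL] = self.gl
        row[_kernel.VK] = self.VK
        row[_kernel.VNA] = self.VNa
        row[_kernel.VL] = self.Vl
        row[_kernel.VCA] = self.VCa
        row[_kernel.MCA_HALF] = self.mca_half
        row[_kernel.MCA_SLOPE] = self.mca_slope
        row[_kernel.MCA_TAU] = self.mca_tau
        row[_kernel.HCA_HALF] = self.hca_half
        row[_kernel.HCA_SLOPE] = self.hca_slope
        row[_kernel.HCA_TAU] = self.hca_tau
        return row


#: network-wide constants shared by every neuron in the whole-brain model
CELEGANS_CONSTANTS = NeuronParams()


def classical_squid_params(gl: float = 0.3) -> NeuronParams:
    """Textbook squid-axon parameterization (Cm 1, gNa 120, gK 36,
    VNa 50, VK -77, Vl -54.4) used for the bifurcation scan."""
    return NeuronParams(
        Cm=1.0, gK=36.0, gNa=120.0, gCa=0.0, gl=gl,
        VK=-77.0, VNa=50.0, Vl=-54.4,
    )


@dataclass
class MembraneState:
    V: float
    m: float
    n: float
    h: float
    mca: float = 0.0
    hca: float = 1.0

    def __post_init__(self) -> None:
        for gate in ("m", "n", "h", "mca", "hca"):
            x = getattr(self, gate)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"gating variable {gate} = {x} outside [0, 1]")


@dataclass(frozen=True)
class StimulusProtocol:
    """A constant current step on one neuron over [t_on, t_off) ms."""

    target: str
    amplitude: float  # nA (1 nA == 1 uA/cm^2 by default)
    t_on: float = 0.0
    t_off: float = math.inf

    def __post_init__(self) -> None:
        if not (0 <= self.t_on < self.t_off):
            raise ValueError("need 0 <= t_on < t_off")


@dataclass
class VoltageTrace:
    """Recorded membrane potentials on a shared time grid (ms / mV)."""

    times: np.ndarray
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or (len(t) > 1 and not np.all(np.diff(t) > 0)):
            raise ValueError("times must be strictly increasing")
        self.times = t
        for name, v in self.data.items():
            v = np.asarray(v, dtype=float)
            if v.shape != t.shape:
                raise ValueError(f"trace {name!r} length mismatch")
            self.data[name] = v

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name]

    @property
    def names(self) -> list[str]:
        return list(self.data)

    def single(self) -> np.ndarray:
        (v,) = self.data.values()
        return v

    def window(self, t_lo: float, t_hi: float) -> "VoltageTrace":
        mask = (self.times >= t_lo) & (self.times <= t_hi)
        return VoltageTrace(self.times[mask],
                            {k: v[mask] for k, v in self.data.items()})


@dataclass
class ResponseClass:
    """Spike-based classification of one voltage response."""

    kind: str  # silent | single_spike | oscillation
    spike_times: list[float] = field(default_factory=list)
    frequency: Optional[float] = None  # Hz, oscillation only
    burst: bool = False  # >=3 irregular spikes

    @property
    def active(self) -> bool:
        """At least one spike (binary "activated" decoding)."""
        return len(self.spike_times) >= 1


# ---------------------------------------------------------------------------
# gating kinetics

def gating_rates(V: float, params: NeuronParams = CELEGANS_CONSTANTS) -> dict:
    """Opening/closing rates (1/ms) for the five gates at voltage ``V``.

    The m/n/h rates are the classical squid-axon forms with removable
    singularities handled by their limits; the calcium gates are expressed
    as equivalent (alpha, beta) pairs of their Boltzmann steady states and
    fixed time constants.
    """
    V = float(V)
    am, bm = _kernel._rates_m(V)
    ah, bh = _kernel._rates_h(V)
    an, bn = _kernel._rates_n(V)
    minf = 1.0 / (1.0 + math.exp(-(V - params.mca_half) / params.mca_slope))
    hinf = 1.0 / (1.0 + math.exp((V - params.hca_half) / params.hca_slope))
    return {
        "m": (am, bm),
        "n": (an, bn),
        "h": (ah, bh),
        "mca": (minf / params.mca_tau, (1.0 - minf) / params.mca_tau),
        "hca": (hinf / params.hca_tau, (1.0 - hinf) / params.hca_tau),
    }


def steady_state_gates(V: float, params: NeuronParams = CELEGANS_CONSTANTS) -> dict:
    """x_inf = alpha / (alpha + beta) for each gate."""
    return {
        gate: a / (a + b) for gate, (a, b) in gating_rates(V, params).items()
    }


def _steady_current(V: float, params: NeuronParams) -> float:
    x = steady_state_gates(V, params)
    s = MembraneState(V=V, m=x["m"], n=x["n"], h=x["h"],
                      mca=x["mca"], hca=x["hca"])
    return sum(channel_currents(s, params).values())


def resting_potential(params: NeuronParams) -> float:
    """Most hyperpolarized zero of the steady-state I-V curve (mV).

    This is the true fixed point the membrane relaxes to without input;
    initializing there gives a reproducible resting start with no burn-in
    (the leak reversal alone is not a fixed point once the other channels
    carry steady-state current).
    """
    lo = min(params.VK, params.Vl) - 20.0
    grid = np.linspace(lo, 0.0, 481)
    prev_v, prev_i = grid[0], _steady_current(grid[0], params)
    for v in grid[1:]:
        cur = _steady_current(v, params)
        if prev_i < 0.0 <= cur or prev_i > 0.0 >= cur:
            a, b = prev_v, v
            for _ in range(80):
                mid = 0.5 * (a + b)
                if (_steady_current(a, params) < 0.0) == (
                        _steady_current(mid, params) < 0.0):
                    a = mid
                else:
                    b = mid
            return 0.5 * (a + b)
        prev_v, prev_i = v, cur
    raise ValueError("no resting potential found below 0 mV")


def resting_state(params: NeuronParams) -> MembraneState:
    """Initial condition: the resting potential with every gate at its
    steady state there."""
    V0 = resting_potential(params)
    x = steady_state_gates(V0, params)
    return MembraneState(V=V0, m=x["m"], n=x["n"], h=x["h"],
                         mca=x["mca"], hca=x["hca"])


def channel_currents(state: MembraneState, params: NeuronParams) -> dict:
    """Instantaneous current densities IK, INa, ICa, Il (uA/cm^2)."""
    V = state.V
    return {
        "IK": params.gK * state.n**4 * (V - params.VK),
        "INa": params.gNa * state.m**3 * state.h * (V - params.VNa),
        "ICa": params.gCa * state.mca**2 * state.hca * (V - params.VCa),
        "Il": params.gl * (V - params.Vl),
    }


# ---------------------------------------------------------------------------
# gene-scaled conductances

DEFAULT_UNIT_CONDUCTANCE = {"K": 1.0, "Na": 1.0, "Ca": 1.0, "leak": 1.0}


def conductances_from_expression(
    expr: GeneExpressionTable,
    channel_map: ChannelGeneMap,
    unit_conductance: Optional[dict[str, float]] = None,
    base: NeuronParams = CELEGANS_CONSTANTS,
) -> dict[str, NeuronParams]:
    """Per-neuron parameters with maximal conductances scaled linearly from
    gene expression: g_c = unit_c * sum of the mapped genes' levels.

    Capacitance and (unless the map lists leak genes) leak conductance stay
    at the global constants.
    """
    channel_map.check_against(expr)
    units = dict(DEFAULT_UNIT_CONDUCTANCE)
    if unit_conductance:
        units.update(unit_conductance)
    attr = {"K": "gK", "Na": "gNa", "Ca": "gCa", "leak": "gl"}
    out: dict[str, NeuronParams] = {}
    for neuron in expr.neurons:
        overrides = {}
        for channel, genes in channel_map.mapping.items():
            level = sum(expr.level(neuron, gene) for gene in genes)
            overrides[attr[channel]] = units[channel] * level
        out[neuron] = replace(base, **overrides)
    return out


# ---------------------------------------------------------------------------
# simulation

def simulate_neuron(
    params: NeuronParams,
    protocol: Optional[StimulusProtocol],
    dt: float = 0.01,
    T: float = 500.0,
    record_stride: int = 1,
    na_scale: float = 1.0,
    initial: Optional[MembraneState] = None,
) -> VoltageTrace:
    """Integrate one isolated neuron from its resting state.

    The trace covers [0, T] with sample spacing ``record_stride * dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    s0 = initial if initial is not None else resting_state(params)
    name = protocol.target if protocol is not None else "neuron"
    V = np.array([s0.V])
    m = np.array([s0.m]); n = np.array([s0.n]); h = np.array([s0.h])
    mca = np.array([s0.mca]); hca = np.array([s0.hca])
    P = params.as_row()[None, :]
    empty_i = np.empty(0, dtype=np.int64)
    empty_f = np.empty(0, dtype=np.float64)
    armed = np.empty(0, dtype=np.uint8)
    if protocol is not None and protocol.amplitude != 0.0:
        stim_t = np.array([0], dtype=np.int64)
        stim_amp = np.array([protocol.amplitude * na_scale])
        stim_on = np.array([protocol.t_on])
        stim_off = np.array([min(protocol.t_off, 1e300)])
    else:
        stim_t, stim_amp = empty_i, empty_f
        stim_on = stim_off = empty_f
    nsteps = int(round(T / dt))
    nrec = nsteps // record_stride + 1
    out = np.empty((1, nrec))
    status, bad_step, _ = _kernel.run_kernel(
        V, m, n, h, mca, hca, P,
        empty_i, empty_i, empty_f, empty_f, empty_f, empty_f, armed,
        -30.0, 1.0,
        stim_t, stim_amp, stim_on, stim_off,
        dt, nsteps, np.array([0], dtype=np.int64), record_stride, out,
    )
    if status == _kernel.STATUS_BLOWUP:
        raise IntegrationError(bad_step * dt, name)
    times = np.arange(nrec) * (record_stride * dt)
    return VoltageTrace(times, {name: out[0]})


# ---------------------------------------------------------------------------
# spike analysis

def detect_spikes(
    values: np.ndarray | VoltageTrace,
    times: Optional[np.ndarray] = None,
    crossing: float = 0.0,
    refractory: float = 2.0,
) -> list[float]:
    """Times of upward crossings of ``crossing`` separated by at least the
    refractory interval (linear interpolation between samples)."""
    if isinstance(values, VoltageTrace):
        times = values.times
        values = values.single()
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if v.size == 0:
        return []
    above = v >= crossing
    idx = np.flatnonzero(~above[:-1] & above[1:])
    spikes: list[float] = []
    last = -math.inf
    for i in idx:
        frac = (crossing - v[i]) / (v[i + 1] - v[i])
        tc = t[i] + frac * (t[i + 1] - t[i])
        if tc - last >= refractory:
            spikes.append(float(tc))
            last = tc
    return spikes


#: maximum interspike-interval coefficient of variation still called periodic
OSCILLATION_CV = 0.2


def classify_response(
    trace: VoltageTrace,
    window: Optional[tuple[float, float]] = None,
    crossing: float = 0.0,
    refractory: float = 2.0,
) -> ResponseClass:
    """Classify a voltage response as silent, single_spike or oscillation.

    0 spikes -> silent; 1-2 -> single_spike; >=3 with ISI CV below
    ``OSCILLATION_CV`` -> oscillation with frequency 1 / mean ISI; >=3
    irregular spikes -> single_spike with the burst flag set.
    """
    if window is not None:
        trace = trace.window(*window)
    spikes = detect_spikes(trace, crossing=crossing, refractory=refractory)
    if len(spikes) == 0:
        return ResponseClass("silent", [])
    if len(spikes) <= 2:
        return ResponseClass("single_spike", spikes)
    isi = np.diff(spikes)
    cv = float(np.std(isi) / np.mean(isi))
    if cv < OSCILLATION_CV:
        freq_hz = 1000.0 / float(np.mean(isi))
        return ResponseClass("oscillation", spikes, frequency=freq_hz)
    return ResponseClass("single_spike", spikes, burst=True)


def _sustained_oscillation(
    params: NeuronParams, amplitude: float, dt: float, T: float
) -> bool:
    """True when a constant current step elicits periodic firing that
    persists through the second half of the run."""
    trace = simulate_neuron(
        params, StimulusProtocol("probe", amplitude, 0.0, T), dt=dt, T=T,
        record_stride=max(1, int(round(0.1 / dt))),
    )
    return classify_response(trace, window=(T / 2.0, T)).kind == "oscillation"


def find_critical_leak(
    params: NeuronParams = None,
    amplitude: float = 6.25,
    bracket: tuple[float, float] = (0.25, 0.35),
    tol: float = 1e-6,
    dt: float = 0.01,
    T: float = 500.0,
) -> float:
    """Bisect on the leak conductance for the boundary between sustained
    periodic firing and a non-oscillatory response under a constant
    suprathreshold current.

    Default probe: 6.25 nA, just above the classical model's onset of
    repetitive firing from rest at standard leak, which places the boundary
    at the literature value near 0.2994 mS/cm^2.
    """
    if params is None:
        params = classical_squid_params()
    lo, hi = bracket
    if not lo < hi:
        raise ValueError("bracket must satisfy lo < hi")
    c_lo = _sustained_oscillation(replace(params, gl=lo), amplitude, dt, T)
    c_hi = _sustained_oscillation(replace(params, gl=hi), amplitude, dt, T)
    if c_lo == c_hi:
        raise ValueError(
            f"bracket [{lo}, {hi}] does not straddle the oscillation "
            f"boundary (both classify {'oscillatory' if c_lo else 'quiet'})"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _sustained_oscillation(replace(params, gl=mid), amplitude, dt, T) == c_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def find_threshold_amplitude(
    params: NeuronParams,
    lo: float = 0.0,
    hi: float = 200.0,
    tol: float = 0.01,
    dt: float = 0.01,
    T: float = 200.0,
    t_on: float = 10.0,
    t_off: float = 190.0,
) -> float:
    """Smallest stimulus amplitude (nA) eliciting at least one spike under
    the standard decision-window protocol, by bisection."""

    def spikes(amp: float) -> bool:
        trace = simulate_neuron(
            params, StimulusProtocol("probe", amp, t_on, t_off), dt=dt, T=T)
        return len(detect_spikes(trace)) >= 1

    if spikes(lo):
        return lo
    if not spikes(hi):
        raise ValueError(f"no spike up to {hi} nA; widen the search range")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if spikes(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
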