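"""Network engine: assemble a connectome into a simulatable model and
advance all neurons and synapses on a shared clock.

Update scheme is synchronous (Jacobi): every synapse reads its presynaptic
voltage from the previous step, so evaluation order cannot change results
and runs are bit-reproducible for a fixed configuration.  Convergence of
the one-step-delay coupling is guarded by the dt-halving tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernel
from .config import RunConfig
from .connectome import ChannelGeneMap, Connectome, GeneExpressionTable
from .membrane import (
    CELEGANS_CONSTANTS,
    IntegrationError,
    NeuronParams,
    StimulusProtocol,
    VoltageTrace,
    conductances_from_expression,
    detect_spikes,
    resting_state,
)
from .synapse import reversal_for_polarity

__all__ = ["NetworkModel", "RunRecord", "build_network", "run"]


@dataclass
class RunRecord:
    """Everything needed to inspect or replay one simulation run."""

    config: dict
    protocols: list[StimulusProtocol]
    trace: VoltageTrace
    spikes: dict[str, list[float]]
    T: float
    dt: float

    def save(self, outdir: str | Path) -> None:
        """metadata JSON + traces CSV (time, neuron, V) + spike raster CSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": self.config,
            "protocols": [dataclasses.asdict(p) for p in self.protocols],
            "T": self.T,
            "dt": self.dt,
        }
        (outdir / "metadata.json").write_text(json.dumps(meta, indent=1, default=float))
        rows = []
        for name in self.trace.names:
            v = self.trace[name]
            rows.append(pd.DataFrame(
                {"time_ms": self.trace.times, "neuron": name, "V_mV": v}))
        pd.concat(rows, ignore_index=True).to_csv(outdir / "traces.csv", index=False)
        raster = [(n, t) for n, ts in self.spikes.items() for t in ts]
        pd.DataFrame(raster, columns=["neuron", "time_ms"]).to_csv(
            outdir / "spikes.csv", index=False)


class NetworkModel:
    """A connectome compiled to flat state/parameter arrays.

    The model itself is immutable run-to-run: :func:`run` always starts
    from the stored resting initial state, so repeated calls are
    independent and deterministic.
    """

    def __init__(
        self,
        connectome: Connectome,
        params_by_neuron: dict[str, NeuronParams],
        config: RunConfig,
    ):
        self.connectome = connectome
        self.config = config
        self.names = list(connectome.neuron_names)
        self.index = {n: i for i, n in enumerate(self.names)}
        n = len(self.names)
        self.P = np.empty((n, _kernel.NPARAM))
        self._params = params_by_neuron
        v0, m0, n0g, h0, mca0, hca0 = (np.empty(n) for _ in range(6))
        for i, name in enumerate(self.names):
            p = params_by_neuron[name]
            self.P[i] = p.as_row()
            s = resting_state(p)
            v0[i], m0[i], n0g[i], h0[i] = s.V, s.m, s.n, s.h
            mca0[i], hca0[i] = s.mca, s.hca
        self._init_state = (v0, m0, n0g, h0, mca0, hca0)
        syn = connectome.synapses
        self.pre = np.array([self.index[s.pre] for s in syn], dtype=np.int64)
        self.post = np.array([self.index[s.post] for s in syn], dtype=np.int64)
        self.w = np.array([s.weight for s in syn], dtype=float)
        self.tau = np.array([s.tau for s in syn], dtype=float)
        self.e = np.array(
            [reversal_for_polarity(s.polarity) for s in syn], dtype=float)

    @property
    def n_neurons(self) -> int:
        return len(self.names)

    @property
    def n_synapses(self) -> int:
        return len(self.pre)

    def params_for(self, name: str) -> NeuronParams:
        return self._params[name]

    def initial_voltages(self) -> np.ndarray:
        return self._init_state[0].copy()

    def motor_names(self) -> list[str]:
        return self.connectome.by_class("motor")


def build_network(
    connectome: Connectome,
    gene_expression: Optional[GeneExpressionTable] = None,
    channel_map: Optional[ChannelGeneMap] = None,
    config: Optional[RunConfig] = None,
    unit_conductance: Optional[dict[str, float]] = None,
    base_params: NeuronParams = CELEGANS_CONSTANTS,
) -> NetworkModel:
    """Compile a validated connectome (plus optional gene-expression
    scaling) into a :class:`NetworkModel`.

    Per-neuron parameters resolve in order: global constants, then
    gene-scaled conductances when expression data is supplied, then any
    explicit per-neuron ``params`` carried on the neuron records.
    """
    connectome.validate()
    config = config or RunConfig()
    params: dict[str, NeuronParams] = {
        name: base_params for name in connectome.neuron_names}
    if gene_expression is not None:
        if channel_map is None:
            raise ValueError("gene expression supplied without a channel map")
        scaled = conductances_from_expression(
            gene_expression, channel_map, unit_conductance, base=base_params)
        for name, p in scaled.items():
            if name in params:
                params[name] = p
    for rec in connectome.neurons:
        if rec.params is not None:
            params[rec.name] = rec.params
    return NetworkModel(connectome, params, config)


def run(
    network: NetworkModel,
    protocols: Sequence[StimulusProtocol],
    T: float,
    dt: Optional[float] = None,
    record: Optional[Sequence[str]] = None,
    record_stride: Optional[int] = None,
) -> RunRecord:
    """Advance the whole network from rest over [0, T] ms.

    ``record`` defaults to all neurons; sampling every ``record_stride``
    steps (default: about one sample per 0.1 ms, full resolution when dt
    is coarser).
    """
    cfg = network.config
    dt = cfg.integrator.dt if dt is None else dt
    if dt <= 0:
        raise ValueError("dt must be > 0")
    for p in protocols:
        if p.target not in network.index:
            raise KeyError(f"protocol target {p.target!r} not in network")
    record = list(record) if record is not None else list(network.names)
    rec_idx = np.array([network.index[r] for r in record], dtype=np.int64)
    if record_stride is None:
        record_stride = max(1, int(round(0.1 / dt)))

    v0, m0, n0, h0, mca0, hca0 = (a.copy() for a in network._init_state)
    g = np.zeros(network.n_synapses)
    armed = np.ones(network.n_synapses, dtype=np.uint8)
    dec = np.exp(-dt / network.tau) if network.n_synapses else np.empty(0)

    if protocols:
        stim_t = np.array([network.index[p.target] for p in protocols],
                          dtype=np.int64)
        stim_amp = np.array(
            [p.amplitude * cfg.integrator.na_scale for p in protocols])
        stim_on = np.array([p.t_on for p in protocols])
        stim_off = np.array([min(p.t_off, 1e300) for p in protocols])
    else:
        stim_t = np.empty(0, dtype=np.int64)
        stim_amp = stim_on = stim_off = np.empty(0)

    nsteps = int(round(T / dt))
    nrec = nsteps // record_stride + 1
    out = np.empty((len(rec_idx), nrec))
    status, bad_step, bad_neuron = _kernel.run_kernel(
        v0, m0, n0, h0, mca0, hca0, network.P,
        network.pre, network.post, g, network.e, network.w, dec, armed,
        cfg.synapse.threshold, cfg.synapse.gain,
        stim_t, stim_amp, stim_on, stim_off,
        dt, nsteps, rec_idx, record_stride, out,
    )
    if status == _kernel.STATUS_BLOWUP:
        raise IntegrationError(bad_step * dt, network.names[bad_neuron])
    times = np.arange(nrec) * (record_stride * dt)
    trace = VoltageTrace(times, {name: out[i] for i, name in enumerate(record)})
    spikes = {
        name: detect_spikes(
            trace[name], times,
            crossing=cfg.spike.crossing, refractory=cfg.spike.refractory)
        for name in record
    }
    return RunRecord(
        config=cfg.to_dict(), protocols=list(protocols), trace=trace,
        spikes=spikes, T=T, dt=dt,
    )
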