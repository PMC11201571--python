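"""Circuit discovery by stimulus sweeps.

A functional sensory->motor circuit shows up as a motor neuron whose
response class changes with the current injected into one sensory neuron.
Sweeping a strictly increasing amplitude grid with a fresh network state
per amplitude and classifying every motor response yields per-sensory
reports: the activation threshold (first non-silent amplitude) and the
maximal contiguous oscillation range, in the layout of the whole-brain
circuit summary table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .membrane import (
    ResponseClass,
    StimulusProtocol,
    VoltageTrace,
    classify_response,
)
from .network import NetworkModel, run

__all__ = [
    "SweepResult",
    "CircuitReport",
    "sweep_stimulus",
    "summarize_circuit",
    "discover_all",
    "reports_to_frame",
    "export_reports",
]


@dataclass
class SweepResult:
    sensory: str
    grid: list[float]  # nA, strictly increasing
    responses: dict[str, list[ResponseClass]]  # motor -> one class per amplitude

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if len(g) == 0 or (len(g) > 1 and not np.all(np.diff(g) > 0)):
            raise ValueError("grid must be nonempty and strictly increasing")
        for motor, classes in self.responses.items():
            if len(classes) != len(g):
                raise ValueError(f"motor {motor!r}: one classification per amplitude")


@dataclass
class CircuitReport:
    sensory: str
    responsive_motors: list[str]
    activation_threshold: Optional[float]  # nA, None when all silent
    oscillation_range: Optional[tuple[float, float]]  # nA
    response_mode: str  # oscillation | single_spike | silent
    errors: list[str] = field(default_factory=list)


def sweep_stimulus(
    network: NetworkModel,
    sensory: str,
    lo: float,
    hi: float,
    step: float,
    T: float = 500.0,
    dt: Optional[float] = None,
    stim_window: tuple[float, float] = (50.0, 450.0),
    motors: Optional[Sequence[str]] = None,
) -> SweepResult:
    """Classify every motor neuron's response at each amplitude of the grid
    lo, lo+step, ..., <= hi.  Each amplitude runs from a fresh resting
    state; classification is restricted to the stimulation window.
    """
    if lo >= hi:
        raise ValueError("need lo < hi")
    if step <= 0:
        raise ValueError("step must be > 0")
    if sensory not in network.index:
        raise KeyError(f"unknown neuron {sensory!r}")
    rec = network.connectome.neuron(sensory)
    if rec.neuron_class != "sensory":
        import warnings

        warnings.warn(f"{sensory!r} is a {rec.neuron_class}, not a sensory neuron")
    motors = list(motors) if motors is not None else network.motor_names()
    grid = [lo + i * step for i in range(int(np.floor((hi - lo) / step + 1e-9)) + 1)]
    responses: dict[str, list[ResponseClass]] = {m: [] for m in motors}
    t_on, t_off = stim_window
    cfg = network.config.spike
    for amp in grid:
        record = run(
            network,
            [StimulusProtocol(sensory, amp, t_on, t_off)],
            T=T, dt=dt, record=motors,
        )
        wtrace = record.trace.window(t_on, t_off)
        for m in motors:
            cls = classify_response(
                VoltageTrace(wtrace.times, {m: wtrace[m]}),
                crossing=cfg.crossing, refractory=cfg.refractory,
            )
            responses[m].append(cls)
    return SweepResult(sensory=sensory, grid=grid, responses=responses)


def summarize_circuit(sweep: SweepResult) -> CircuitReport:
    """Condense a sweep into a circuit-table row.

    threshold = first amplitude with any non-silent motor; the oscillation
    range is the maximal contiguous grid run where at least one motor
    classifies as oscillation; response_mode is oscillation when such a run
    exists, else single_spike (or silent when nothing responds).
    """
    grid = sweep.grid
    any_nonsilent = [
        any(sweep.responses[m][i].kind != "silent" for m in sweep.responses)
        for i in range(len(grid))
    ]
    any_osc = [
        any(sweep.responses[m][i].kind == "oscillation" for m in sweep.responses)
        for i in range(len(grid))
    ]
    responsive = sorted(
        m for m, classes in sweep.responses.items()
        if any(c.kind != "silent" for c in classes)
    )
    threshold = next(
        (grid[i] for i, ns in enumerate(any_nonsilent) if ns), None)
    best: Optional[tuple[int, int]] = None
    start = None
    for i, osc in enumerate(any_osc + [False]):
        if osc and start is None:
            start = i
        elif not osc and start is not None:
            if best is None or (i - start) > (best[1] - best[0]):
                best = (start, i - 1)
            start = None
    osc_range = (grid[best[0]], grid[best[1]]) if best is not None else None
    if osc_range is not None:
        mode = "oscillation"
    elif responsive:
        mode = "single_spike"
    else:
        mode = "silent"
    return CircuitReport(
        sensory=sweep.sensory,
        responsive_motors=responsive,
        activation_threshold=threshold,
        oscillation_range=osc_range,
        response_mode=mode,
    )


def discover_all(
    network: NetworkModel,
    sensory_list: Sequence[str],
    lo: float,
    hi: float,
    step: float,
    T: float = 500.0,
    dt: Optional[float] = None,
) -> list[CircuitReport]:
    """Sweep + summarize each listed sensory neuron, ordered by name.
    Per-sensory failures are reported on the affected row; the run
    continues."""
    reports = []
    for sensory in sorted(sensory_list):
        try:
            sweep = sweep_stimulus(network, sensory, lo, hi, step, T=T, dt=dt)
            reports.append(summarize_circuit(sweep))
        except Exception as exc:  # aggregated, not fatal
            reports.append(CircuitReport(
                sensory=sensory, responsive_motors=[],
                activation_threshold=None, oscillation_range=None,
                response_mode="silent", errors=[str(exc)],
            ))
    return reports


def reports_to_frame(reports: Sequence[CircuitReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sensory": r.sensory,
            "motor_list": ";".join(r.responsive_motors),
            "threshold_nA": r.activation_threshold,
            "osc_lo_nA": r.oscillation_range[0] if r.oscillation_range else None,
            "osc_hi_nA": r.oscillation_range[1] if r.oscillation_range else None,
            "mode": r.response_mode,
            "errors": ";".join(r.errors),
        }
        for r in reports
    )


def export_reports(
    reports: Sequence[CircuitReport], path: str | Path, format: str = "csv"
) -> None:
    path = Path(path)
    frame = reports_to_frame(reports)
    if format == "csv":
        frame.to_csv(path, index=False)
    elif format == "json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=1))
    else:
        raise ValueError(f"unknown format {format!r}")
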