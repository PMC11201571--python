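"""Chemical synapse dynamics: thresholded transmission with conductance
increment and exponential decay.

Each synapse keeps a conductance g that decays as g' = -g/tau and jumps by
the weight w exactly once per upward crossing of the presynaptic voltage
threshold (-30 mV by default).  The postsynaptic current I = g (V_post - e)
is subtracted in the membrane equation, so an excitatory synapse (e = 0 mV)
depolarizes a hyperpolarized cell and an inhibitory one (e = -80 mV)
hyperpolarizes a cell above -80 mV.  Gap junctions are deliberately absent.

These functions are the reference semantics for the jitted network kernel;
the engine tests assert the two agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SynapseState",
    "E_EXCITATORY",
    "E_INHIBITORY",
    "TRANSMISSION_THRESHOLD",
    "reversal_for_polarity",
    "decay",
    "on_presynaptic_voltage",
    "synaptic_current",
]

E_EXCITATORY = 0.0     # mV
E_INHIBITORY = -80.0   # mV
TRANSMISSION_THRESHOLD = -30.0  # mV, presynaptic voltage gate


def reversal_for_polarity(polarity: int) -> float:
    """Polarity encodes the reversal potential: +1 -> 0 mV, -1 -> -80 mV."""
    if polarity == +1:
        return E_EXCITATORY
    if polarity == -1:
        return E_INHIBITORY
    raise ValueError(f"polarity must be +1 or -1, got {polarity}")


@dataclass
class SynapseState:
    """Instantaneous state of one synaptic contact."""

    w: float               # conductance increment per presynaptic spike
    tau: float             # decay constant, ms
    e: float = E_EXCITATORY  # reversal potential, mV
    g: float = 0.0         # instantaneous conductance (weight units)
    armed: bool = True     # ready to fire on the next upward crossing

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be > 0")
        if self.g < 0:
            raise ValueError("g must be >= 0")


def decay(g: float, dt: float, tau: float) -> float:
    """Exact exponential decay update: g -> g * exp(-dt/tau)."""
    if dt <= 0 or tau <= 0:
        raise ValueError("dt and tau must be > 0")
    return g * math.exp(-dt / tau)


def on_presynaptic_voltage(
    state: SynapseState,
    V_pre: float,
    threshold: float = TRANSMISSION_THRESHOLD,
) -> SynapseState:
    """Edge-triggered transmission.

    On an upward crossing (armed and V_pre >= threshold) the conductance
    jumps by w exactly once; the synapse re-arms when V_pre falls back
    below threshold.  Holding the presynaptic voltage above threshold for
    any number of steps therefore produces a single increment.
    """
    if state.armed and V_pre >= threshold:
        state.g += state.w
        state.armed = False
    elif V_pre < threshold:
        state.armed = True
    return state


def synaptic_current(g: float, V_post: float, e: float) -> float:
    """I = g (V_post - e), subtracted in the postsynaptic membrane
    equation like the ionic currents."""
    return g * (V_post - e)
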