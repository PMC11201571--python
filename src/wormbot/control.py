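"""Encoding/decoding layer between the neural network and the robot.

Two control mechanisms:

* **Binary foraging** — the distance to a target point maps to a Gaussian
  "food" concentration f(x) = A exp(-k x^2); the step-to-step concentration
  change encodes as a stimulus I = 51 + (f_now - f_prev) nA on the sensory
  neuron ASHL.  When the motor neuron VB1 fires (concentration rose, i.e.
  the robot moved closer), the previous heading is kept; when VB1 stays
  silent a fresh uniformly random heading is drawn.  Gradient climbing with
  random reorientation, the worm's chemotaxis strategy.

* **Four-region locomotion** — the legs partition into heading-relative
  regions A-D; each occupied region stimulates its OLQ sensory neuron
  (A->OLQDR, B->OLQDL, C->OLQVR, D->OLQVL), each OLQ drives exactly one
  RMD motor neuron, and active RMDs decode to leg commands: RMDDR -> B
  extends, RMDVR -> D extends, RMDDL -> A shrinks, RMDVL -> C shrinks.
  Extending the trailing legs while shrinking the leading ones rolls the
  robot toward the heading.

Sensing and commands travel as line-delimited JSON control messages over an
in-process queue or a local socket, so the network side and the robot side
can run as two decoupled programs; both transports give identical episodes.
"""

from __future__ import annotations

import json
import math
import socket
from collections import deque
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .config import RobotConfig, RunConfig
from .connectome import Motif, generate_synthetic_connectome
from .membrane import (
    CELEGANS_CONSTANTS,
    ResponseClass,
    StimulusProtocol,
    VoltageTrace,
    classify_response,
)
from .network import NetworkModel, build_network, run
from .robot import LegArray, RegionAssignment, assign_regions
from .robot import default_state as robot_default_state
from .robot import settle as robot_settle
from .robot import step as robot_step

__all__ = [
    "ForagingEnv",
    "ControlDecision",
    "LocomotionCommand",
    "ControlMessage",
    "MessageError",
    "concentration",
    "stimulus_from_concentration",
    "decide_foraging",
    "encode_regions",
    "decode_locomotion",
    "decode_frequency_to_length",
    "build_foraging_network",
    "build_locomotion_network",
    "run_foraging_episode",
    "run_locomotion_episode",
    "ForagingResult",
    "LocomotionResult",
    "encode_message",
    "decode_message",
    "InProcessTransport",
    "SocketTransport",
    "make_inprocess_pair",
    "make_socketpair_transports",
    "OLQ_FOR_REGION",
    "RMD_REGION",
    "REGION_ACTION",
]

# ---------------------------------------------------------------------------
# concentration field and stimulus encoder

#: baseline stimulus; equals the calibrated activation boundary of the
#: foraging circuit, so the sign of the concentration change decides firing
STIMULUS_BASE = 51.0


@dataclass
class ForagingEnv:
    """Gaussian 'food' field around a target point."""

    target: tuple[float, float] = (0.0, 0.0)
    amplitude: float = 1.0e7   # concentration at the target
    decay: float = 2.0         # Gaussian decay coefficient, 1/m^2
    step_length: float = 0.1   # m moved per decision
    tolerance: float = 0.15    # m, arrival radius

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.decay <= 0:
            raise ValueError("amplitude and decay must be > 0")

    def distance(self, pos: Sequence[float]) -> float:
        dx = pos[0] - self.target[0]
        dy = pos[1] - self.target[1]
        return math.hypot(dx, dy)


def concentration(x: float, env: Optional[ForagingEnv] = None) -> float:
    """f(x) = A exp(-k x^2) with the huge default amplitude that keeps even
    tiny displacements above the encoder's activation margin near the
    target."""
    env = env or ForagingEnv()
    if x < 0:
        raise ValueError("distance must be >= 0")
    return env.amplitude * math.exp(-env.decay * x * x)


def stimulus_from_concentration(
    f_now: float,
    f_prev: float,
    base: float = STIMULUS_BASE,
    clamp: tuple[float, float] = (0.0, 200.0),
) -> float:
    """I = base + (f_now - f_prev) nA, clamped to the explored dynamic
    range (the raw difference is unbounded for large concentration jumps)."""
    if not (math.isfinite(f_now) and math.isfinite(f_prev)):
        raise ValueError("concentrations must be finite")
    return float(min(max(base + (f_now - f_prev), clamp[0]), clamp[1]))


@dataclass
class ControlDecision:
    kind: str  # keep_direction | new_random_direction
    heading: np.ndarray  # unit 2-vector

    def __post_init__(self) -> None:
        h = np.asarray(self.heading, dtype=float)
        n = np.linalg.norm(h)
        if n < 1e-12:
            raise ValueError("heading must be nonzero")
        self.heading = h / n


def decide_foraging(
    vb1_response: ResponseClass,
    prev_heading: Sequence[float],
    rng: np.random.Generator,
) -> ControlDecision:
    """Any spiking counts as activated -> keep the heading; silence draws a
    new heading uniformly on the circle."""
    if vb1_response.active:
        return ControlDecision("keep_direction", np.asarray(prev_heading, float))
    angle = rng.uniform(0.0, 2.0 * math.pi)
    return ControlDecision(
        "new_random_direction", np.array([math.cos(angle), math.sin(angle)]))


# ---------------------------------------------------------------------------
# four-region encode/decode

OLQ_FOR_REGION = {"A": "OLQDR", "B": "OLQDL", "C": "OLQVR", "D": "OLQVL"}
RMD_REGION = {"RMDDR": "B", "RMDVR": "D", "RMDDL": "A", "RMDVL": "C"}
#: what an *active* RMD commands its region to do
REGION_ACTION = {"B": "extend", "D": "extend", "A": "shrink", "C": "shrink"}
#: default OLQ drive, above all four activation thresholds (max 94 nA)
OLQ_AMPLITUDE = 100.0


@dataclass
class LocomotionCommand:
    """Per-region actions plus the per-leg target lengths they imply."""

    actions: dict[str, str]  # region -> extend | shrink | hold
    leg_targets: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        bad = set(self.actions.values()) - {"extend", "shrink", "hold"}
        if bad:
            raise ValueError(f"unknown action(s) {sorted(bad)}")
        ext = {r for r, a in self.actions.items() if a == "extend"}
        shr = {r for r, a in self.actions.items() if a == "shrink"}
        if (ext & {"A", "C"}) or (shr & {"B", "D"}):
            raise ValueError(
                "four-region rule violated: only B/D extend and only A/C shrink")

    def targets_for(self, legs: LegArray, assignment: RegionAssignment) -> np.ndarray:
        targets = legs.lengths.copy()
        for i, region in assignment.mapping.items():
            action = self.actions.get(region, "hold")
            if action == "extend":
                targets[i] = legs.L_max
            elif action == "shrink":
                targets[i] = legs.L_min
        return targets


def encode_regions(
    assignment: RegionAssignment,
    amplitude: float = OLQ_AMPLITUDE,
    t_on: float = 10.0,
    t_off: float = 190.0,
) -> list[StimulusProtocol]:
    """One constant-current protocol on the OLQ neuron of every occupied
    region."""
    if not assignment.mapping:
        raise ValueError("empty region assignment")
    return [
        StimulusProtocol(OLQ_FOR_REGION[region], amplitude, t_on, t_off)
        for region in assignment.occupied()
    ]


def decode_locomotion(
    rmd_responses: dict[str, ResponseClass],
) -> LocomotionCommand:
    """Active RMDs command their region (extend B/D, shrink A/C); inactive
    ones hold."""
    missing = set(RMD_REGION) - set(rmd_responses)
    if missing:
        raise ValueError(f"missing RMD response(s): {sorted(missing)}")
    actions = {region: "hold" for region in "ABCD"}
    for rmd, region in RMD_REGION.items():
        if rmd_responses[rmd].active:
            actions[region] = REGION_ACTION[region]
    return LocomotionCommand(actions)


def decode_frequency_to_length(
    response: ResponseClass,
    freq_range: tuple[float, float],
    length_range: tuple[float, float],
) -> tuple[float, bool]:
    """Continuous spike-frequency -> leg-length decoder (the first,
    muscle-like mechanism): an affine map from [f_min, f_max] Hz onto
    [L_min, L_max] m, clamped at the ends.

    Returns (length, valid); a silent or single-spike response cannot carry
    a frequency and yields (L_min, False).
    """
    f_min, f_max = freq_range
    L_min, L_max = length_range
    if not (f_max > f_min and L_max > L_min):
        raise ValueError("ranges must be increasing")
    if response.kind != "oscillation" or response.frequency is None:
        return L_min, False
    frac = (response.frequency - f_min) / (f_max - f_min)
    return L_min + min(max(frac, 0.0), 1.0) * (L_max - L_min), True


# ---------------------------------------------------------------------------
# synthetic circuit fixtures

# Per-neuron potassium conductances calibrated (bisection on the decision
# protocol, frozen) so each sensory neuron first reaches the -30 mV
# chemical-transmission threshold -- and hence first drives its motor
# neuron -- at the printed circuit-table stimulus: ASHL at the 51 nA
# baseline, the OLQ dorsal/ventral-left neurons at 91 nA, OLQVR at 94 nA.
CALIBRATED_GK = {
    "ASHL": 1045.76,
    "OLQDL": 1591.99,
    "OLQDR": 1591.99,
    "OLQVL": 1591.99,
    "OLQVR": 1628.60,
}
#: strong relay weight so a sensory spike reliably propagates to the motor
FIXTURE_WEIGHT = 3.0


def _sensory_params(gK: float):
    return replace(CELEGANS_CONSTANTS, gK=gK)


def build_foraging_network(config: Optional[RunConfig] = None) -> NetworkModel:
    """Two-layer ASHL -> VB1 motif (through one relay interneuron) with the
    activation boundary calibrated to the 51 nA stimulus baseline."""
    conn = generate_synthetic_connectome(
        1, 1, 1, motifs=[Motif("ASHL", "VB1", +1, FIXTURE_WEIGHT)],
        seed=0, p_feedforward=0.0,
        sensory_names=["ASHL"], motor_names=["VB1"],
    )
    conn.neuron("ASHL").params = _sensory_params(CALIBRATED_GK["ASHL"])
    return build_network(conn, config=config)


def build_locomotion_network(config: Optional[RunConfig] = None) -> NetworkModel:
    """The four OLQ -> RMD one-to-one circuits with calibrated thresholds."""
    sens = ["OLQDL", "OLQDR", "OLQVL", "OLQVR"]
    mots = ["RMDDR", "RMDDL", "RMDVR", "RMDVL"]
    motifs = [
        Motif("OLQDL", "RMDDR", +1, FIXTURE_WEIGHT),
        Motif("OLQDR", "RMDDL", +1, FIXTURE_WEIGHT),
        Motif("OLQVL", "RMDVR", +1, FIXTURE_WEIGHT),
        Motif("OLQVR", "RMDVL", +1, FIXTURE_WEIGHT),
    ]
    conn = generate_synthetic_connectome(
        4, 1, 4, motifs=motifs, seed=0, p_feedforward=0.0,
        sensory_names=sens, motor_names=mots,
    )
    for name in sens:
        conn.neuron(name).params = _sensory_params(CALIBRATED_GK[name])
    return build_network(conn, config=config)


def _classify_motors(
    network: NetworkModel,
    protocols: list[StimulusProtocol],
    motors: Sequence[str],
    window: float,
    dt: float,
) -> dict[str, ResponseClass]:
    t_on = min(p.t_on for p in protocols)
    t_off = max(p.t_off for p in protocols)
    rec = run(network, protocols, T=window, dt=dt, record=list(motors))
    wtrace = rec.trace.window(t_on, t_off)
    cfg = network.config.spike
    return {
        m: classify_response(
            VoltageTrace(wtrace.times, {m: wtrace[m]}),
            crossing=cfg.crossing, refractory=cfg.refractory)
        for m in motors
    }


# ---------------------------------------------------------------------------
# control messages and transports

SCHEMA_VERSION = 1


class MessageError(ValueError):
    """Malformed or unsupported control message."""


@dataclass
class ControlMessage:
    step: int
    role: str  # "robot->bnn" | "bnn->robot"
    payload: dict
    schema_version: int = SCHEMA_VERSION

    ROLES = ("robot->bnn", "bnn->robot")

    def __post_init__(self) -> None:
        if self.role not in self.ROLES:
            raise MessageError(f"unknown role {self.role!r}")


def encode_message(msg: ControlMessage) -> str:
    """One JSON object per line."""
    return json.dumps(
        {"step": msg.step, "role": msg.role, "payload": msg.payload,
         "schema_version": msg.schema_version},
        separators=(",", ":"),
    ) + "\n"


def decode_message(line: str) -> ControlMessage:
    try:
        data = json.loads(line)
    except json.JSONDecodeError as exc:
        raise MessageError(
            f"unparseable control message at position {exc.pos}: {exc.msg}"
        ) from exc
    if not isinstance(data, dict):
        raise MessageError("control message must be a JSON object")
    version = data.get("schema_version")
    if version != SCHEMA_VERSION:
        raise MessageError(f"unsupported schema version {version!r}")
    missing = {"step", "role", "payload"} - set(data)
    if missing:
        raise MessageError(f"missing field(s) {sorted(missing)}")
    return ControlMessage(
        step=int(data["step"]), role=data["role"], payload=data["payload"])


class InProcessTransport:
    """One endpoint of a pair of in-memory line queues."""

    def __init__(self, inbox: deque, outbox: deque):
        self._inbox = inbox
        self._outbox = outbox

    def send(self, msg: ControlMessage) -> None:
        self._outbox.append(encode_message(msg))

    def recv(self) -> ControlMessage:
        if not self._inbox:
            raise MessageError("no message pending")
        return decode_message(self._inbox.popleft())

    def close(self) -> None:
        pass


def make_inprocess_pair() -> tuple[InProcessTransport, InProcessTransport]:
    a_to_b: deque = deque()
    b_to_a: deque = deque()
    return (InProcessTransport(b_to_a, a_to_b),
            InProcessTransport(a_to_b, b_to_a))


class SocketTransport:
    """Line-delimited JSON over a connected local socket."""

    def __init__(self, sock: socket.socket):
        self._sock = sock
        self._rfile = sock.makefile("r", encoding="utf-8", newline="\n")

    def send(self, msg: ControlMessage) -> None:
        self._sock.sendall(encode_message(msg).encode("utf-8"))

    def recv(self) -> ControlMessage:
        line = self._rfile.readline()
        if not line:
            raise MessageError("connection closed")
        return decode_message(line)

    def close(self) -> None:
        self._rfile.close()
        self._sock.close()


def make_socketpair_transports() -> tuple[SocketTransport, SocketTransport]:
    """Two connected endpoints over a local socket pair (no network)."""
    a, b = socket.socketpair()
    return SocketTransport(a), SocketTransport(b)


# ---------------------------------------------------------------------------
# closed-loop episodes

@dataclass
class ForagingResult:
    trajectory: np.ndarray  # rows: step, x, y, heading_x, heading_y, stimulus
    decisions: list[str]
    converged: bool
    steps: int

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.trajectory,
            columns=["step", "x", "y", "heading_x", "heading_y", "stimulus_nA"],
        ).assign(decision=self.decisions).to_csv(path, index=False)


def run_foraging_episode(
    env: ForagingEnv,
    network: Optional[NetworkModel] = None,
    seed: int = 0,
    start: tuple[float, float] = (2.5, 0.0),
    max_steps: int = 400,
    decision_window: float = 200.0,
    dt: float = 0.01,
    initial_heading: Optional[Sequence[float]] = None,
    transports: Optional[tuple] = None,
    mover: Optional[Callable] = None,
) -> ForagingResult:
    """Closed-loop gradient climbing with the binary ASHL->VB1 circuit.

    Per step: measure distance, encode the concentration change as a
    stimulus, run the network from a fresh state for the decision window,
    decode VB1 into keep/random, advance one step of ``env.step_length``
    (the default mover is a point mass).  Terminates on arrival within
    ``env.tolerance`` or after ``max_steps``; non-convergence is a reported
    outcome, not an error.  All sensing and commands round-trip through the
    message transport (an in-process pair by default).
    """
    network = network or build_foraging_network()
    rng = np.random.default_rng(seed)
    robot_end, bnn_end = transports or make_inprocess_pair()
    pos = np.array(start, dtype=float)
    if initial_heading is None:
        angle = rng.uniform(0.0, 2.0 * math.pi)
        heading = np.array([math.cos(angle), math.sin(angle)])
    else:
        heading = np.asarray(initial_heading, dtype=float)
        heading = heading / np.linalg.norm(heading)
    f_prev = concentration(env.distance(pos), env)
    rows = []
    decisions: list[str] = []
    converged = False
    steps = 0
    for k in range(max_steps):
        d = env.distance(pos)
        if d <= env.tolerance:
            converged = True
            break
        f_now = concentration(d, env)
        stim = stimulus_from_concentration(f_now, f_prev)
        robot_end.send(ControlMessage(
            k, "robot->bnn",
            {"concentration": f_now, "stimulus_nA": stim}))
        sense = bnn_end.recv()
        amp = float(sense.payload["stimulus_nA"])
        responses = _classify_motors(
            network, [StimulusProtocol("ASHL", amp, 10.0, decision_window - 10.0)],
            ["VB1"], window=decision_window, dt=dt)
        decision = decide_foraging(responses["VB1"], heading, rng)
        bnn_end.send(ControlMessage(
            k, "bnn->robot",
            {"kind": decision.kind, "heading": list(decision.heading)}))
        command = robot_end.recv()
        heading = np.asarray(command.payload["heading"], dtype=float)
        if mover is None:
            pos = pos + env.step_length * heading
        else:
            pos = np.asarray(mover(pos, heading, env), dtype=float)
        rows.append([k, pos[0], pos[1], heading[0], heading[1], stim])
        decisions.append(command.payload["kind"])
        f_prev = f_now
        steps = k + 1
    else:
        converged = env.distance(pos) <= env.tolerance
    traj = np.array(rows) if rows else np.empty((0, 6))
    return ForagingResult(traj, decisions, converged, steps)


@dataclass
class LocomotionResult:
    positions: np.ndarray  # (n_steps + 1, 3)
    leg_lengths: np.ndarray  # (n_steps + 1, 12)
    displacement: np.ndarray
    azimuth_deg: float


def run_locomotion_episode(
    heading_deg: float,
    n_steps: int = 150,
    network: Optional[NetworkModel] = None,
    robot_cfg: Optional[RobotConfig] = None,
    control_period: float = 0.25,
    robot_dt: float = 2e-3,
    decision_window: float = 200.0,
    bnn_dt: float = 0.02,
    amplitude: float = OLQ_AMPLITUDE,
) -> LocomotionResult:
    """Closed-loop four-region walking in a commanded horizontal direction.

    Per control step: assign leg regions from the current attitude, encode
    each occupied region as an OLQ stimulus, run the network from a fresh
    state, decode the RMD responses into extend/shrink commands, then
    integrate the rigid-body dynamics for one control period while the
    legs slew toward their targets.
    """
    network = network or build_locomotion_network()
    cfg = robot_cfg or RobotConfig()
    heading = np.array([math.cos(math.radians(heading_deg)),
                        math.sin(math.radians(heading_deg))])
    legs = LegArray.from_config(cfg)
    legs.lengths[:] = 0.5 * (cfg.leg_min + cfg.leg_max)
    state = robot_settle(robot_default_state(legs, drop=0.01), legs, cfg,
                         duration=0.5, dt=robot_dt)
    positions = [state.pos.copy()]
    lengths = [legs.lengths.copy()]
    n_sub = int(round(control_period / robot_dt))
    for _ in range(n_steps):
        assignment = assign_regions(legs, heading, state.quat)
        protocols = encode_regions(assignment, amplitude=amplitude)
        responses = _classify_motors(
            network, protocols, list(RMD_REGION), decision_window, bnn_dt)
        command = decode_locomotion(responses)
        targets = command.targets_for(legs, assignment)
        for _ in range(n_sub):
            state = robot_step(state, legs, targets, cfg, robot_dt)
        positions.append(state.pos.copy())
        lengths.append(legs.lengths.copy())
    positions = np.array(positions)
    lengths = np.array(lengths)
    disp = positions[-1] - positions[0]
    azimuth = math.degrees(math.atan2(disp[1], disp[0]))
    return LocomotionResult(positions, lengths, disp, azimuth)
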