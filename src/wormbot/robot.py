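"""Quaternion rigid-body dynamics of the 12-legged spherical robot.

The robot is a central sphere with 12 radially telescoping legs mounted at
icosahedron-vertex directions.  Its 13-component state is position,
attitude quaternion, inertial velocity and body-frame angular velocity.
Translation follows Newton (v' = F/m), attitude the quaternion kinematic
equation, and rotation the full Euler equations (which reduce exactly to
w_i' = M_i / J_i for the uniform-sphere case of equal moments).  Ground is
the z = 0 plane; each leg tip gets a spring-damper normal force plus
Coulomb-capped tangential friction.  Integration is RK4 with quaternion
renormalization each step.

The four-region partition buckets each leg's world-frame axis by its angle
in the vertical plane spanned by the heading and up: front-lower legs form
region A, rear-lower D, rear-upper B, front-upper C.  Shrinking A and C
while extending B and D tips the support polygon backward under the body,
so the robot rolls toward the heading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import RobotConfig

__all__ = [
    "RobotState",
    "LegArray",
    "RegionAssignment",
    "REGIONS",
    "icosahedron_axes",
    "quat_to_rot",
    "quaternion_derivative",
    "translational_rhs",
    "rotational_rhs",
    "contact_and_leg_forces",
    "assign_regions",
    "step",
    "settle",
    "default_state",
]

REGIONS = ("A", "B", "C", "D")


#: default yaw (degrees) of the leg layout; keeps every axis clear of the
#: exact region-boundary planes for the cardinal headings, where the
#: four-region gait would otherwise degenerate into a symmetric bounce
DEFAULT_LAYOUT_YAW = 15.0


def icosahedron_axes(yaw_deg: float = 0.0) -> np.ndarray:
    """12 unit vectors at icosahedron vertices (uniform leg layout),
    optionally yawed about +z."""
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    verts = [
        (0.0, 1.0, phi), (0.0, -1.0, phi), (0.0, 1.0, -phi), (0.0, -1.0, -phi),
        (1.0, phi, 0.0), (-1.0, phi, 0.0), (1.0, -phi, 0.0), (-1.0, -phi, 0.0),
        (phi, 0.0, 1.0), (-phi, 0.0, 1.0), (phi, 0.0, -1.0), (-phi, 0.0, -1.0),
    ]
    axes = np.array(verts, dtype=float)
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    if yaw_deg:
        c, s = math.cos(math.radians(yaw_deg)), math.sin(math.radians(yaw_deg))
        axes = axes @ np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])
    return axes


@dataclass
class RobotState:
    """13-component rigid-body state."""

    pos: np.ndarray = field(default_factory=lambda: np.zeros(3))   # m, inertial
    quat: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0, 0]))
    vel: np.ndarray = field(default_factory=lambda: np.zeros(3))   # m/s, inertial
    omega: np.ndarray = field(default_factory=lambda: np.zeros(3))  # rad/s, body

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        self.quat = np.asarray(self.quat, dtype=float)
        self.vel = np.asarray(self.vel, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)

    def copy(self) -> "RobotState":
        return RobotState(self.pos.copy(), self.quat.copy(),
                          self.vel.copy(), self.omega.copy())

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.pos, self.quat, self.vel, self.omega])


@dataclass
class LegArray:
    """The 12 telescoping legs: fixed body-frame axes and current lengths."""

    axes: np.ndarray = field(
        default_factory=lambda: icosahedron_axes(DEFAULT_LAYOUT_YAW))  # (12, 3)
    lengths: np.ndarray = field(default_factory=lambda: np.full(12, 0.24))
    L_min: float = 0.24
    L_max: float = 0.50
    rate: float = 0.25  # m/s slew limit

    def __post_init__(self) -> None:
        self.axes = np.asarray(self.axes, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        n = len(self.axes)
        if len(self.lengths) != n:
            raise ValueError("axes/lengths length mismatch")
        for i in range(n):
            for j in range(i + 1, n):
                if np.allclose(self.axes[i], self.axes[j]):
                    raise ValueError(f"legs {i} and {j} share an axis")
        self.clamp()

    @classmethod
    def from_config(cls, cfg: RobotConfig) -> "LegArray":
        return cls(lengths=np.full(12, cfg.leg_min), L_min=cfg.leg_min,
                   L_max=cfg.leg_max, rate=cfg.leg_rate)

    def clamp(self) -> None:
        np.clip(self.lengths, self.L_min, self.L_max, out=self.lengths)

    def slew_toward(self, targets: np.ndarray, dt: float) -> np.ndarray:
        """Rate-limited leg extension speeds actually applied over dt."""
        delta = np.clip(targets - self.lengths, -self.rate * dt, self.rate * dt)
        self.lengths += delta
        self.clamp()
        return delta / dt

    def copy(self) -> "LegArray":
        return LegArray(self.axes.copy(), self.lengths.copy(),
                        self.L_min, self.L_max, self.rate)


def quat_to_rot(q: np.ndarray) -> np.ndarray:
    """Body->world rotation matrix of a unit quaternion (w, x, y, z)."""
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def quaternion_derivative(q: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Attitude kinematics: lambda' = 1/2 Omega(w) lambda with body-frame w."""
    l0, l1, l2, l3 = q
    wx, wy, wz = omega
    return 0.5 * np.array([
        -l1 * wx - l2 * wy - l3 * wz,
        l0 * wx - l3 * wy + l2 * wz,
        l3 * wx + l0 * wy - l1 * wz,
        -l2 * wx + l1 * wy + l0 * wz,
    ])


def translational_rhs(state: RobotState, F: np.ndarray, mass: float) -> tuple:
    """x' = v, v' = F / m (inertial frame)."""
    if mass <= 0:
        raise ValueError("mass must be > 0")
    return state.vel.copy(), np.asarray(F, dtype=float) / mass


def rotational_rhs(omega: np.ndarray, M: np.ndarray, inertia) -> np.ndarray:
    """Full Euler equations in the body principal frame.

    J_x w_x' + (J_z - J_y) w_y w_z = M_x (and cyclic); with equal moments
    the gyroscopic terms vanish and w_i' = M_i / J_i exactly.
    """
    Jx, Jy, Jz = inertia
    if min(Jx, Jy, Jz) <= 0:
        raise ValueError("moments of inertia must be > 0")
    wx, wy, wz = omega
    Mx, My, Mz = M
    return np.array([
        (Mx - (Jz - Jy) * wy * wz) / Jx,
        (My - (Jx - Jz) * wz * wx) / Jy,
        (Mz - (Jy - Jx) * wx * wy) / Jz,
    ])


def contact_and_leg_forces(
    state: RobotState,
    legs: LegArray,
    cfg: RobotConfig,
    leg_rates: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Total external force (world) and torque (body) on the robot.

    Gravity, plus for every leg tip below z = 0 a spring-damper normal
    force and tangential friction capped by the Coulomb cone; the shell
    itself contacts the ground the same way as a fallback.
    """
    R = quat_to_rot(state.quat)
    if leg_rates is None:
        leg_rates = np.zeros(len(legs.axes))
    omega_w = R @ state.omega

    # contact points: 12 leg tips + the lowest point of the shell
    axes_w = legs.axes @ R.T
    r = np.vstack([axes_w * legs.lengths[:, None],
                   [[0.0, 0.0, -cfg.shell_radius]]])
    vel = state.vel + np.cross(omega_w, r)
    vel[:-1] += axes_w * leg_rates[:, None]
    z = state.pos[2] + r[:, 2]
    pen = np.maximum(-z, 0.0)
    active = pen > 0.0
    fn = np.where(
        active,
        np.maximum(cfg.contact_stiffness * pen
                   - cfg.contact_damping * vel[:, 2], 0.0),
        0.0,
    )
    f = np.zeros_like(r)
    f[:, 2] = fn
    vt = vel.copy()
    vt[:, 2] = 0.0
    speed = np.linalg.norm(vt, axis=1)
    slipping = active & (speed > 1e-12)
    if np.any(slipping):
        ft = np.minimum(cfg.friction * fn[slipping],
                        cfg.tangential_damping * speed[slipping])
        f[slipping, :2] -= (ft / speed[slipping])[:, None] * vt[slipping, :2]
    F = f.sum(axis=0) + np.array([0.0, 0.0, -cfg.mass * cfg.gravity])
    M_world = np.cross(r, f).sum(axis=0)
    return F, R.T @ M_world


@dataclass
class RegionAssignment:
    """Partition of the legs into the four heading-relative regions."""

    mapping: dict[int, str]

    def __post_init__(self) -> None:
        bad = set(self.mapping.values()) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown region label(s) {sorted(bad)}")

    def legs_in(self, region: str) -> list[int]:
        return sorted(i for i, r in self.mapping.items() if r == region)

    def occupied(self) -> list[str]:
        return sorted(set(self.mapping.values()))


def assign_regions(
    legs: LegArray, heading: np.ndarray, quat: np.ndarray
) -> RegionAssignment:
    """Bucket each leg into regions A-D by its world-frame angle theta in
    the vertical (heading, up) plane.

    theta is measured from the heading toward up; quadrants [0, 90) ->
    front-upper C, [90, 180) -> rear-upper B, [180, 270) -> rear-lower D,
    [270, 360) -> front-lower A.  A leg exactly on a boundary joins the
    lower-theta region.
    """
    hin = np.asarray(heading, dtype=float)
    h = np.array([hin[0], hin[1], 0.0])
    norm = np.linalg.norm(h)
    if norm < 1e-12:
        raise ValueError("heading must be a nonzero horizontal vector")
    h /= norm
    R = quat_to_rot(quat)
    order = ("C", "B", "D", "A")  # quadrants counterclockwise from heading
    mapping: dict[int, str] = {}
    for i, axis in enumerate(legs.axes):
        w = R @ axis
        theta = math.degrees(math.atan2(w[2], float(w[:2] @ h[:2]))) % 360.0
        # boundary tie-break: exact multiples of 90 join the region below
        idx = int(math.floor(((theta - 1e-9) % 360.0) / 90.0))
        mapping[i] = order[idx]
    return RegionAssignment(mapping)


def default_state(legs: LegArray, drop: float = 0.0) -> RobotState:
    """Rest pose: center high enough that the lowest tips just touch."""
    clearance = -min(float(a[2]) * L for a, L in zip(legs.axes, legs.lengths))
    return RobotState(pos=np.array([0.0, 0.0, clearance + drop]))


def step(
    state: RobotState,
    legs: LegArray,
    commands: Optional[np.ndarray],
    cfg: RobotConfig,
    dt: float,
) -> RobotState:
    """One RK4 step of the rigid-body dynamics with leg slewing.

    ``commands`` are per-leg target lengths (None holds current lengths);
    lengths slew within the rate limit at the start of the step and stay
    fixed during the substeps.  The quaternion is renormalized afterwards.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if commands is not None:
        rates = legs.slew_toward(np.asarray(commands, dtype=float), dt)
    else:
        rates = np.zeros(len(legs.axes))

    def rhs(s: RobotState):
        F, M = contact_and_leg_forces(s, legs, cfg, leg_rates=rates)
        dpos, dvel = translational_rhs(s, F, cfg.mass)
        dquat = quaternion_derivative(s.quat, s.omega)
        domega = rotational_rhs(s.omega, M, cfg.inertia)
        return dpos, dquat, dvel, domega

    def advance(s: RobotState, k, f: float) -> RobotState:
        return RobotState(
            s.pos + f * k[0], s.quat + f * k[1],
            s.vel + f * k[2], s.omega + f * k[3])

    k1 = rhs(state)
    k2 = rhs(advance(state, k1, dt / 2))
    k3 = rhs(advance(state, k2, dt / 2))
    k4 = rhs(advance(state, k3, dt))
    new = RobotState(
        state.pos + dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]),
        state.quat + dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]),
        state.vel + dt / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]),
        state.omega + dt / 6 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3]),
    )
    if not np.all(np.isfinite(new.as_vector())):
        raise RuntimeError("robot dynamics blew up")
    new.quat /= np.linalg.norm(new.quat)
    return new


def settle(
    state: RobotState, legs: LegArray, cfg: RobotConfig,
    duration: float = 1.0, dt: float = 1e-3,
) -> RobotState:
    """Integrate with held legs until transients damp out (drop to rest)."""
    s = state
    for _ in range(int(round(duration / dt))):
        s = step(s, legs, None, cfg, dt)
    return s
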