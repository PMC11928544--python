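"""Limb- and joint-level mechanical power and work.

The limb-level analysis follows the individual-limbs method: each limb's
external power on the body is the dot product of its ground reaction force
with the whole-body COM velocity, and total limb power adds the peripheral
power — the rate of change of the limb segments' kinetic energy measured
relative to the COM. Joint powers are moment × angular velocity per
rotational degree of freedom (summed across DOFs) and force × linear
velocity for translational DOFs, including the socket pistoning DOF of a
socket-suspended prosthesis. Ankle-foot power uses a unified deformable
segment treatment: everything distal to the shank is lumped together and the
GRF is taken to act at the centre of pressure moving as a point fixed to the
shank, plus the free moment acting on shank rotation.

Work per stride is the time integral of power on the native (unnormalized)
time base; positive and negative components integrate the positive and
negative parts of the power only, so positive + negative == net exactly
under the shared trapezoidal quadrature. Sign convention throughout: energy
absorption is negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gait_io import GRAVITY, GaitTrial, SegmentState
from .preprocess import Stride

__all__ = [
    "PowerCurve",
    "WorkSummary",
    "PeakMetrics",
    "central_difference",
    "whole_body_com",
    "limb_com_power",
    "peripheral_power",
    "limb_power",
    "joint_rotational_power",
    "joint_translational_power",
    "socket_power",
    "ud_ankle_foot_power",
    "work_components",
    "peak_metrics",
    "com_energy_rate",
]


@dataclass
class PowerCurve:
    """A mechanical power trace (W, or W/kg if mass-normalized)."""

    values: np.ndarray
    source: str  # {limb, limb_com, peripheral, hip, knee, ankle_foot_UD, socket}
    limb: str = ""
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("power curve contains non-finite values")


@dataclass
class WorkSummary:
    """Net/positive/negative work over one stride (J, or J/kg if normalized)."""

    net: float
    positive: float
    negative: float
    source: str = ""
    limb: str = ""
    speed: float = float("nan")
    speed_bin: str = ""
    interface: str = ""
    participant: str = ""

    def __post_init__(self):
        if self.positive < 0 or self.negative > 0:
            raise ValueError("positive work must be >= 0 and negative <= 0")
        if abs((self.positive + self.negative) - self.net) > 1e-9 * max(
            1.0, abs(self.net)
        ):
            raise ValueError("net work must equal positive + negative")


@dataclass
class PeakMetrics:
    """Per-stride peak loading and hip kinetic metrics (mass-normalized)."""

    max_vgrf: float  # N/kg, over stance
    peak_hip_flexion_moment: float  # N·m/kg, late-stance flexor extremum
    peak_hip_angular_velocity: float  # rad/s, over stride


def central_difference(x: np.ndarray, dt: float) -> np.ndarray:
    """2nd-order central differences; one-sided 2nd-order at the endpoints."""
    x = np.asarray(x, dtype=float)
    d = np.empty_like(x)
    d[1:-1] = (x[2:] - x[:-2]) / (2 * dt)
    d[0] = (-3 * x[0] + 4 * x[1] - x[2]) / (2 * dt)
    d[-1] = (3 * x[-1] - 4 * x[-2] + x[-3]) / (2 * dt)
    return d


def whole_body_com(segments: list[SegmentState]) -> tuple[np.ndarray, np.ndarray]:
    """Mass-weighted aggregation of segment COM states.

    Returns ``(com_pos, com_vel)`` as (n, 3) arrays.
    """
    total = sum(s.mass for s in segments)
    if total <= 0:
        raise ValueError("total segment mass must be > 0")
    pos = sum(s.mass * s.com_pos for s in segments) / total
    vel = sum(s.mass * s.com_vel for s in segments) / total
    return pos, vel


def limb_com_power(
    grf: np.ndarray,
    com_vel: np.ndarray,
    body_mass: float | None = None,
    limb: str = "",
) -> PowerCurve:
    """External power of one limb on the body: GRF · COM velocity.

    Gravity does not appear here — it is shared by both limbs and handled in
    whole-body energy bookkeeping, not attributed to either limb.
    """
    grf = np.asarray(grf, dtype=float)
    com_vel = np.asarray(com_vel, dtype=float)
    if grf.shape != com_vel.shape:
        raise ValueError("GRF and COM-velocity series have mismatched shapes")
    p = np.einsum("ij,ij->i", grf, com_vel)
    if body_mass:
        return PowerCurve(p / body_mass, "limb_com", limb, normalized=True)
    return PowerCurve(p, "limb_com", limb)


def peripheral_power(
    segments: list[SegmentState],
    com_vel: np.ndarray,
    rate: float,
    limb: str = "",
    body_mass: float | None = None,
) -> PowerCurve:
    """Rate of change of limb-segment kinetic energy relative to the COM.

    KE_s(t) = ½ m_s |v_s − v_COM|² + ½ ω_sᵀ I_s ω_s, summed over the limb's
    segments and differentiated with central differences.
    """
    com_vel = np.asarray(com_vel, dtype=float)
    ke = np.zeros(com_vel.shape[0])
    for s in segments:
        v_rel = s.com_vel - com_vel
        ke += 0.5 * s.mass * np.einsum("ij,ij->i", v_rel, v_rel)
        ke += 0.5 * np.einsum("ij,jk,ik->i", s.ang_vel, s.inertia, s.ang_vel)
    p = central_difference(ke, 1.0 / rate)
    if body_mass:
        return PowerCurve(p / body_mass, "peripheral", limb, normalized=True)
    return PowerCurve(p, "peripheral", limb)


def limb_power(
    grf: np.ndarray,
    com_vel: np.ndarray,
    segments: list[SegmentState],
    rate: float,
    limb: str = "",
    body_mass: float | None = None,
) -> PowerCurve:
    """Total limb power: external COM power plus peripheral power."""
    ext = limb_com_power(grf, com_vel, body_mass, limb)
    per = peripheral_power(segments, com_vel, rate, limb, body_mass)
    return PowerCurve(ext.values + per.values, "limb", limb, normalized=bool(body_mass))


def joint_rotational_power(
    moments: np.ndarray,
    ang_vels: np.ndarray,
    source: str = "joint",
    limb: str = "",
    body_mass: float | None = None,
) -> PowerCurve:
    """Sum over DOFs of joint moment × joint angular velocity.

    ``moments`` and ``ang_vels`` are (n, n_dof) with matching DOF order
    (1-D inputs are treated as a single DOF).
    """
    m = np.atleast_2d(np.asarray(moments, dtype=float).T).T
    w = np.atleast_2d(np.asarray(ang_vels, dtype=float).T).T
    if m.shape != w.shape:
        raise ValueError(
            f"moment DOFs {m.shape} do not match angular-velocity DOFs {w.shape}"
        )
    p = np.einsum("ij,ij->i", m, w)
    if body_mass:
        return PowerCurve(p / body_mass, source, limb, normalized=True)
    return PowerCurve(p, source, limb)


def joint_translational_power(
    forces: np.ndarray,
    lin_vels: np.ndarray,
    source: str = "joint_translation",
    limb: str = "",
    body_mass: float | None = None,
) -> PowerCurve:
    """Sum over translational DOFs of joint force × linear velocity."""
    return joint_rotational_power(forces, lin_vels, source, limb, body_mass)


def socket_power(
    piston_force: np.ndarray,
    piston_vel: np.ndarray,
    interface: str = "socket",
    limb: str = "prosthetic",
    body_mass: float | None = None,
) -> PowerCurve:
    """Translational power at the socket pistoning degree of freedom.

    ``piston_force`` is the axial interface force along the femur long axis
    (positive in compression); ``piston_vel`` the rate of the proximal-positive
    pistoning displacement. Compression under rising load absorbs energy
    (negative power); energy returned to the limb is positive.
    """
    if interface != "socket":
        raise ValueError("socket DOF absent: trial uses an osseointegrated interface")
    f = np.asarray(piston_force, dtype=float)
    v = np.asarray(piston_vel, dtype=float)
    if f.shape != v.shape:
        raise ValueError("piston force/velocity length mismatch")
    # compression: displacement grows proximally while the load opposes it
    p = -f * v
    if body_mass:
        return PowerCurve(p / body_mass, "socket", limb, normalized=True)
    return PowerCurve(p, "socket", limb)


def ud_ankle_foot_power(
    grf: np.ndarray,
    cop: np.ndarray,
    shank: SegmentState,
    free_moment: np.ndarray | None = None,
    stance_mask: np.ndarray | None = None,
    force_threshold: float = 20.0,
    limb: str = "",
    body_mass: float | None = None,
) -> PowerCurve:
    """Unified deformable segment power of the ankle-foot complex.

    Lumps everything distal to the shank into one deformable body:

        P_UD = F · v_COP-as-shank-point + M_free · ω_shank,
        v_COP-as-shank-point = v_shank + ω_shank × (r_COP − r_shank).

    Swing samples (``stance_mask`` false, or COP undefined) are set to 0.
    A defined load (|F| above ``force_threshold``) with an undefined COP is
    an inconsistency and raises.
    """
    grf = np.asarray(grf, dtype=float)
    cop = np.asarray(cop, dtype=float)
    fmag = np.linalg.norm(grf, axis=1)
    cop_ok = np.all(np.isfinite(cop), axis=1)
    if stance_mask is None:
        stance_mask = cop_ok & (fmag > force_threshold)
    stance_mask = np.asarray(stance_mask, dtype=bool)
    bad = stance_mask & ~cop_ok & (fmag > force_threshold)
    if np.any(bad):
        raise ValueError(
            f"COP undefined while |F| > {force_threshold} N at sample "
            f"{int(np.nonzero(bad)[0][0])}"
        )
    r = np.where(cop_ok[:, None], cop, 0.0) - shank.com_pos
    v_point = shank.com_vel + np.cross(shank.ang_vel, r)
    p = np.einsum("ij,ij->i", grf, v_point)
    if free_moment is not None:
        p = p + np.einsum(
            "ij,ij->i", np.asarray(free_moment, dtype=float), shank.ang_vel
        )
    p = np.where(stance_mask, p, 0.0)
    if body_mass:
        return PowerCurve(p / body_mass, "ankle_foot_UD", limb, normalized=True)
    return PowerCurve(p, "ankle_foot_UD", limb)


def work_components(
    power: PowerCurve | np.ndarray,
    time: np.ndarray,
    body_mass: float | None = None,
    **meta,
) -> WorkSummary:
    """Decompose one stride of power into net/positive/negative work.

    Composite trapezoid on the native time base; the positive and negative
    parts are integrated separately so their sum equals the net integral
    exactly. ``body_mass`` converts J to J/kg (skip if the power curve is
    already mass-normalized).
    """
    p = power.values if isinstance(power, PowerCurve) else np.asarray(power, float)
    time = np.asarray(time, dtype=float)
    if p.size == 0 or time.size == 0:
        raise ValueError("empty stride")
    if p.shape != time.shape:
        raise ValueError("power and time length mismatch")
    scale = 1.0 / body_mass if body_mass else 1.0
    pos = float(np.trapezoid(np.maximum(p, 0.0), time)) * scale
    neg = float(np.trapezoid(np.minimum(p, 0.0), time)) * scale
    if isinstance(power, PowerCurve):
        meta.setdefault("source", power.source)
        meta.setdefault("limb", power.limb)
    return WorkSummary(net=pos + neg, positive=pos, negative=neg, **meta)


def peak_metrics(
    vgrf: np.ndarray,
    hip_flexion_moment: np.ndarray,
    hip_angular_velocity: np.ndarray,
    stride: Stride,
    body_mass: float,
    late_stance_window: tuple[float, float] = (0.30, 0.60),
) -> PeakMetrics:
    """Per-stride peak loading and hip metrics.

    ``max_vgrf`` is the stride maximum of the vertical GRF (N/kg). The late
    stance hip flexion moment peak is the extremum in the flexor (positive)
    direction within ``late_stance_window`` of the gait cycle; the hip
    angular-velocity peak is the stride maximum. Moments are mass-normalized.
    """
    i0, i1 = stride.i_start, stride.i_end
    if i1 > len(vgrf) or i1 > len(hip_flexion_moment):
        raise ValueError("channels do not cover the stride")
    n = i1 - i0
    w0 = i0 + int(np.floor(late_stance_window[0] * n))
    w1 = i0 + int(np.ceil(late_stance_window[1] * n))
    if w1 <= w0:
        raise ValueError("late-stance window is empty for this stride")
    return PeakMetrics(
        max_vgrf=float(np.max(vgrf[i0:i1])) / body_mass,
        peak_hip_flexion_moment=float(np.max(hip_flexion_moment[w0:w1])) / body_mass,
        peak_hip_angular_velocity=float(np.max(hip_angular_velocity[i0:i1])),
    )


def com_energy_rate(
    com_vel: np.ndarray,
    com_height: np.ndarray,
    body_mass: float,
    rate: float,
) -> np.ndarray:
    """d/dt of COM mechanical energy (kinetic + gravitational), W.

    Used for energy-bookkeeping checks: on dynamically consistent data the sum
    of the limbs' external COM powers equals this pointwise.
    """
    v2 = np.einsum("ij,ij->i", com_vel, com_vel)
    e = 0.5 * body_mass * v2 + body_mass * GRAVITY * np.asarray(com_height, float)
    return central_difference(e, 1.0 / rate)
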