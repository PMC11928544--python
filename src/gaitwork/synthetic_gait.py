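"""Synthetic walking trials with known ground-truth energetics.

Two generators produce dynamically consistent steady-state walking:

``point_mass``
    The body is a single point mass; the legs are massless force conduits.
    Per-limb vertical GRF profiles (smoothstep-ramped plateaus scaled by the
    imposed intact:prosthetic loading ratio) and fore-aft braking/propulsion
    profiles are prescribed; their sum defines the COM acceleration, and COM
    velocity/position follow by integration. Newton's law
    F_total = m·(a_COM − g_vec) holds by construction, peripheral power is
    exactly zero, and per-limb peak vGRF equals the imposed asymmetry.

``planar_linkage``
    A 2-D sagittal chain — HAT (head-arms-trunk) plus thigh, shank and foot
    per limb. The pelvis translates at the target speed with a small vertical
    oscillation, the stance foot is flat and stationary, and the swing ankle
    follows a C² (quintic-blended) trajectory; joint angles follow from
    two-link inverse kinematics. Segment velocities/accelerations come from
    one consistent central-difference operator, total GRF from whole-body
    Newton-Euler, per-limb GRF from a smoothstep double-support split, and
    joint moments from bottom-up Newton-Euler inverse dynamics per limb.
    An optional socket pistoning DOF on the prosthetic thigh stores and
    dissipates interface energy with an exactly known dissipated fraction.

All randomness is confined to :func:`add_noise`; generation itself is
deterministic given the configuration.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .energetics import central_difference, limb_com_power, work_components
from .gait_io import GRAVITY, GaitTrial, SegmentState
from .preprocess import detect_contacts

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate",
    "generate_point_mass",
    "generate_planar_linkage",
    "add_noise",
]

G_VEC = np.array([0.0, -GRAVITY, 0.0])

#: Segment mass fractions and lengths (adult anthropometry, sagittal model)
HAT_FRAC = 0.678
THIGH_FRAC = 0.100
SHANK_FRAC = 0.0465
FOOT_FRAC = 0.0145
THIGH_LEN = 0.44
SHANK_LEN = 0.43
ANKLE_HEIGHT = 0.08
HIP_HEIGHT = 0.76
THIGH_COM_FRAC = 0.433  # from proximal end
SHANK_COM_FRAC = 0.433
THIGH_GYR = 0.323  # radius of gyration / length, about COM
SHANK_GYR = 0.302


@dataclass
class SyntheticConfig:
    """Generator parameters; the defaults emulate overground walking at
    1.0 m s⁻¹ by an 85 kg adult (prosthesis included in body mass).

    load_share_asym is the imposed intact:prosthetic peak-vGRF ratio
    (1.0 = symmetric). socket_compliance (m/N) and socket_dissipation_frac
    configure the pistoning interface; compliance 0 means a rigid (OI)
    interface. stride_duration defaults to 1.36 s at 1.0 m s⁻¹, scaled by
    (1/speed)^0.5 at other speeds.
    """

    seed: int = 0
    model: str = "point_mass"
    body_mass: float = 85.0
    speed: float = 1.0
    stride_duration: float | None = None
    n_strides: int = 5
    stance_fraction: float = 0.62
    ramp_fraction: float = 0.30  # of stance, each vGRF ramp (point mass)
    ap_force_scale: float = 0.18  # peak fore-aft force, fraction of body weight
    load_share_asym: float = 1.0
    socket_compliance: float = 0.0
    socket_dissipation_frac: float = 0.0
    noise_sd: dict = field(
        default_factory=lambda: {"force": 2.0, "kinematic": 0.002, "moment": 0.5}
    )
    force_rate: float = 1200.0
    kinematic_rate: float = 120.0
    limb_mass_scale: float = 1.0
    foot_mass_scale: float = 1.0
    participant: str = "P01"

    def __post_init__(self):
        if self.model not in ("point_mass", "planar_linkage"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.load_share_asym <= 0:
            raise ValueError("load_share_asym must be > 0")
        if not (0.0 <= self.socket_dissipation_frac <= 1.0):
            raise ValueError("socket_dissipation_frac must be in [0, 1]")
        if self.stride_duration is None:
            self.stride_duration = 1.36 * (1.0 / self.speed) ** 0.5
        if not (0.5 < self.stance_fraction < 0.8):
            raise ValueError(
                "stance_fraction must be in (0.5, 0.8): lower values create "
                "flight phases (reduce oscillation amplitudes / use running "
                "models), higher are not gait-like"
            )

    @property
    def interface(self) -> str:
        return "socket" if self.socket_compliance > 0 else "OI"


@dataclass
class GroundTruth:
    """Generator-side truth, internally consistent with the emitted channels."""

    events: dict[str, list[int]]  # per-limb strike sample indices (40 N rule)
    stance_windows: dict[str, list[tuple[int, int]]]  # per-limb (on, off) samples
    work: dict[str, dict[str, list[float]]]  # per-limb net/positive/negative, J/kg
    peak_vgrf: dict[str, float]  # N/kg
    socket_dissipation: list[float] = field(default_factory=list)  # J per contact
    socket_stored: list[float] = field(default_factory=list)  # J per contact
    socket_windows: list[tuple[int, int]] = field(default_factory=list)
    speed: float = float("nan")


def _smoothstep(x: np.ndarray) -> np.ndarray:
    """Quintic smoothstep: C² with zero velocity and acceleration at 0 and 1."""
    x = np.clip(x, 0.0, 1.0)
    return x**3 * (10.0 - 15.0 * x + 6.0 * x**2)


def _plateau(u: np.ndarray, ramp: float) -> np.ndarray:
    """Ramp-plateau-ramp window on [0, 1], quintic ramps of width ``ramp``."""
    up = _smoothstep(u / ramp)
    down = _smoothstep((1.0 - u) / ramp)
    w = np.minimum(up, down)
    return np.where((u < 0) | (u > 1), 0.0, w)


def _contact_starts(cfg: SyntheticConfig, phase: float) -> np.ndarray:
    """Stance-onset times of one limb over the trial, including edge partials."""
    T = cfg.stride_duration
    total = cfg.n_strides * T
    k0 = -1  # allow a partial contact entering from before t=0
    ks = np.arange(k0, cfg.n_strides + 1)
    starts = ks * T + phase * T
    ts = cfg.stance_fraction * T
    return starts[(starts + ts > 0) & (starts < total)]


def generate(cfg: SyntheticConfig) -> tuple[GaitTrial, GroundTruth]:
    """Dispatch on ``cfg.model``."""
    if cfg.model == "point_mass":
        return generate_point_mass(cfg)
    return generate_planar_linkage(cfg)


# ---------------------------------------------------------------------------
# point-mass walker
# ---------------------------------------------------------------------------

def generate_point_mass(cfg: SyntheticConfig) -> tuple[GaitTrial, GroundTruth]:
    """Point-mass walker: massless legs, prescribed per-limb GRF profiles.

    Returns the trial (COM carried as a single trunk segment; the trial's
    ``extras`` include the exact COM acceleration) and the ground truth.
    """
    m = cfg.body_mass
    fs = cfg.kinematic_rate
    # snap the stride to an integer sample count so strides span exact
    # periods of the force pattern on the grid
    T = round(cfg.stride_duration * fs) / fs
    cfg = replace(cfg, stride_duration=T)
    n = int(round(cfg.n_strides * T * fs)) + 1
    t = np.arange(n) / fs
    ts = cfg.stance_fraction * T
    r = cfg.ramp_fraction
    R = cfg.load_share_asym

    phases = {"intact": 0.0, "prosthetic": 0.5}
    # stance phase of each limb as an exactly T-periodic function of time,
    # so every stride spans one exact period of the force pattern
    stance_u = {
        limb: np.mod(t - ph * T, T) / ts for limb, ph in phases.items()
    }

    # vertical: ramped plateaus with a speed-scaled mid-stance dip (the
    # M-shape of overground vGRF deepens with speed); scale set so the mean
    # total vGRF carries body weight, preserving the imposed
    # intact:prosthetic peak ratio
    dip = min(0.3 * cfg.speed, 0.6)
    base = {
        limb: _plateau(u, r)
        * (1.0 - dip * np.sin(np.pi * np.clip(u, 0, 1)) ** 2)
        for limb, u in stance_u.items()
    }
    fy = {"prosthetic": base["prosthetic"], "intact": R * base["intact"]}
    tot = fy["prosthetic"] + fy["intact"]
    mean_tot = np.trapezoid(tot, t) / (t[-1] - t[0])
    scale = m * GRAVITY / mean_tot
    fy = {limb: v * scale for limb, v in fy.items()}

    # fore-aft: windowed braking->propulsion wave, zero net impulse per
    # stance; amplitude grows with walking speed, as braking/propulsion
    # impulses do in overground gait
    b = cfg.ap_force_scale * m * GRAVITY * (cfg.speed / 1.0)
    ap_shape = lambda u: -np.sin(2 * np.pi * np.clip(u, 0, 1)) * _plateau(u, r)
    fx = {
        "prosthetic": (2 * b / (1 + R)) * ap_shape(stance_u["prosthetic"]),
        "intact": (2 * b * R / (1 + R)) * ap_shape(stance_u["intact"]),
    }

    # COM state by integration of the prescribed total force
    from scipy.integrate import cumulative_trapezoid

    acc = np.zeros((n, 3))
    acc[:, 0] = (fx["prosthetic"] + fx["intact"]) / m
    acc[:, 1] = (fy["prosthetic"] + fy["intact"]) / m - GRAVITY
    span = t[-1] - t[0]
    vel = np.zeros((n, 3))
    vel[:, 0] = cumulative_trapezoid(acc[:, 0], t, initial=0.0)
    vel[:, 0] += cfg.speed - np.trapezoid(vel[:, 0], t) / span
    vel[:, 1] = cumulative_trapezoid(acc[:, 1], t, initial=0.0)
    vel[:, 1] -= np.trapezoid(vel[:, 1], t) / span
    pos = np.zeros((n, 3))
    pos[:, 0] = cumulative_trapezoid(vel[:, 0], t, initial=0.0)
    pos[:, 1] = 1.0 + cumulative_trapezoid(vel[:, 1], t, initial=0.0)

    trunk = SegmentState(
        name="trunk",
        mass=m,
        inertia=np.zeros((3, 3)),
        com_pos=pos,
        com_vel=vel,
        ang_vel=np.zeros((n, 3)),
        limb_assignment="trunk",
    )
    grf = {}
    for limb in ("prosthetic", "intact"):
        grf[limb] = pd.DataFrame(
            {
                "fx": fx[limb],
                "fy": fy[limb],
                "fz": np.zeros(n),
                "copx": np.full(n, np.nan),
                "copy": np.full(n, np.nan),
                "copz": np.full(n, np.nan),
            }
        )
    trial = GaitTrial(
        time=t,
        rate=fs,
        grf=grf,
        segments=[trunk],
        joints=None,
        body_mass=m,
        meta={
            "participant": cfg.participant,
            "interface": cfg.interface,
            "model": "point_mass",
        },
        extras={"com_acc": acc},
    )
    truth = _ground_truth_from_trial(trial, cfg)
    return trial, truth


def _ground_truth_from_trial(trial: GaitTrial, cfg: SyntheticConfig) -> GroundTruth:
    """Events, stance windows and per-limb work from the clean channels."""
    _, com_vel = _trial_com(trial)
    events, stances, work, peaks = {}, {}, {}, {}
    for limb in trial.limbs:
        ev = detect_contacts(trial.vgrf(limb), trial.rate)
        events[limb] = [e.strike for e in ev]
        stances[limb] = [(e.strike, e.toe_off) for e in ev]
        f3 = trial.grf[limb][["fx", "fy", "fz"]].to_numpy()
        peaks[limb] = float(trial.vgrf(limb).max()) / trial.body_mass
        w = {"net": [], "positive": [], "negative": []}
        for i0, i1 in zip(events[limb][:-1], events[limb][1:]):
            p = limb_com_power(f3[i0 : i1 + 1], com_vel[i0 : i1 + 1], limb=limb)
            ws = work_components(p, trial.time[i0 : i1 + 1], trial.body_mass)
            w["net"].append(ws.net)
            w["positive"].append(ws.positive)
            w["negative"].append(ws.negative)
        work[limb] = w
    return GroundTruth(
        events=events,
        stance_windows=stances,
        work=work,
        peak_vgrf=peaks,
        speed=cfg.speed,
    )


def _trial_com(trial: GaitTrial) -> tuple[np.ndarray, np.ndarray]:
    total = sum(s.mass for s in trial.segments)
    pos = sum(s.mass * s.com_pos for s in trial.segments) / total
    vel = sum(s.mass * s.com_vel for s in trial.segments) / total
    return pos, vel


# ---------------------------------------------------------------------------
# planar linkage walker
# ---------------------------------------------------------------------------

def _two_link_ik(
    hip: np.ndarray, ankle: np.ndarray, a: float, b: float
) -> np.ndarray:
    """Knee position (anterior solution) of a 2-D thigh-shank chain."""
    d_vec = ankle - hip
    d = np.hypot(d_vec[:, 0], d_vec[:, 1])
    if np.any(d > a + b - 1e-6):
        raise ValueError(
            "hip-ankle distance exceeds leg length: foot cannot stay on the "
            "ground during its assigned stance (shorten the stride or lower "
            "the pelvis)"
        )
    f = (a**2 - b**2 + d**2) / (2 * d)
    h = np.sqrt(np.maximum(a**2 - f**2, 0.0))
    u = d_vec / d[:, None]
    n = np.column_stack([-u[:, 1], u[:, 0]])  # anterior of the hip-ankle chord
    return hip + f[:, None] * u + h[:, None] * n


def _unit_omega(u: np.ndarray, dt: float) -> np.ndarray:
    """Angular rate of a 2-D unit-vector series: ω = u × du/dt."""
    du = np.column_stack(
        [central_difference(u[:, 0], dt), central_difference(u[:, 1], dt)]
    )
    return u[:, 0] * du[:, 1] - u[:, 1] * du[:, 0]


def _cross2(r: np.ndarray, f: np.ndarray) -> np.ndarray:
    return r[:, 0] * f[:, 1] - r[:, 1] * f[:, 0]


def _to3(xy: np.ndarray) -> np.ndarray:
    return np.column_stack([xy, np.zeros(len(xy))])


def generate_planar_linkage(cfg: SyntheticConfig) -> tuple[GaitTrial, GroundTruth]:
    """Sagittal-plane 7-segment walker with optional socket pistoning DOF."""
    m = cfg.body_mass
    fs = cfg.kinematic_rate
    T = round(cfg.stride_duration * fs) / fs  # integer samples per stride
    cfg = replace(cfg, stride_duration=T)
    dt = 1.0 / fs
    n = int(round(cfg.n_strides * T * fs)) + 1
    t = np.arange(n) / fs
    ts = cfg.stance_fraction * T
    stride_len = cfg.speed * T

    # pelvis: constant forward speed + small vertical oscillation (2/stride)
    hip = np.column_stack(
        [cfg.speed * t, HIP_HEIGHT + 0.01 * np.cos(4 * np.pi * t / T)]
    )

    phases = {"intact": 0.0, "prosthetic": 0.5}
    starts = {limb: _contact_starts(cfg, ph) for limb, ph in phases.items()}

    ankle, foot_on = {}, {}
    for limb in phases:
        ank = np.zeros((n, 2))
        on = np.zeros(n, dtype=bool)
        t0s = sorted(starts[limb])

        # stance anchors: ankle under the pelvis at mid-stance
        def anchor_for(k):
            return cfg.speed * (t0s[0] + ts / 2) + k * stride_len

        for i, ti in enumerate(t):
            # which contact (if any) covers ti
            k = int(np.floor((ti - t0s[0]) / T))
            t_on = t0s[0] + k * T
            if ti >= t_on + ts:  # in swing after contact k
                tau = (ti - (t_on + ts)) / (T - ts)
                x0 = anchor_for(k)
                ank[i, 0] = x0 + stride_len * _smoothstep(np.array([tau]))[0]
                b = _smoothstep(np.array([tau]))[0]
                bb = _smoothstep(np.array([1 - tau]))[0]
                ank[i, 1] = ANKLE_HEIGHT + 0.05 * (b * bb) / 0.25
            elif ti < t_on:  # in swing before contact k (entering)
                tau = 1.0 - (t_on - ti) / (T - ts)
                x0 = anchor_for(k - 1)
                ank[i, 0] = x0 + stride_len * _smoothstep(np.array([tau]))[0]
                b = _smoothstep(np.array([tau]))[0]
                bb = _smoothstep(np.array([1 - tau]))[0]
                ank[i, 1] = ANKLE_HEIGHT + 0.05 * (b * bb) / 0.25
            else:  # stance: flat, stationary foot
                ank[i] = (anchor_for(k), ANKLE_HEIGHT)
                on[i] = True
        ankle[limb] = ank
        foot_on[limb] = on

    # segment kinematics (one consistent central-difference operator)
    m_th = THIGH_FRAC * m * cfg.limb_mass_scale
    m_sh = SHANK_FRAC * m * cfg.limb_mass_scale
    m_ft = FOOT_FRAC * m * cfg.limb_mass_scale * cfg.foot_mass_scale
    m_hat = m - 2 * (m_th + m_sh + m_ft)
    if m_hat <= 0:
        raise ValueError("limb masses exceed body mass")

    segments: list[SegmentState] = []
    hat_com = hip + np.array([0.0, 0.30])
    hat_vel = np.column_stack(
        [central_difference(hat_com[:, 0], dt), central_difference(hat_com[:, 1], dt)]
    )
    segments.append(
        SegmentState(
            "trunk", m_hat, np.zeros((3, 3)), _to3(hat_com), _to3(hat_vel),
            np.zeros((n, 3)), "trunk",
        )
    )

    kin = {}  # per limb: dict of arrays used by dynamics
    for limb in phases:
        knee = _two_link_ik(hip, ankle[limb], THIGH_LEN, SHANK_LEN)
        u_th = (knee - hip) / THIGH_LEN
        u_sh = (ankle[limb] - knee) / SHANK_LEN
        p_th = hip + THIGH_COM_FRAC * THIGH_LEN * u_th
        p_sh = knee + SHANK_COM_FRAC * SHANK_LEN * u_sh
        p_ft = ankle[limb] + np.array([0.05, -0.03])
        w_th = _unit_omega(u_th, dt)
        w_sh = _unit_omega(u_sh, dt)
        w_ft = np.zeros(n)  # foot stays horizontal throughout
        I_th = m_th * (THIGH_GYR * THIGH_LEN) ** 2
        I_sh = m_sh * (SHANK_GYR * SHANK_LEN) ** 2
        I_ft = m_ft * 0.05**2
        d = {}
        for name, p, w, mass, inert in (
            ("thigh", p_th, w_th, m_th, I_th),
            ("shank", p_sh, w_sh, m_sh, I_sh),
            ("foot", p_ft, w_ft, m_ft, I_ft),
        ):
            v = np.column_stack(
                [central_difference(p[:, 0], dt), central_difference(p[:, 1], dt)]
            )
            a = np.column_stack(
                [central_difference(v[:, 0], dt), central_difference(v[:, 1], dt)]
            )
            d[name] = dict(p=p, v=v, a=a, w=w, alpha=central_difference(w, dt),
                           mass=mass, inertia=inert)
            inertia3 = np.diag([0.0, 0.0, inert])
            segments.append(
                SegmentState(
                    f"{limb}_{name}", mass, inertia3, _to3(p), _to3(v),
                    np.column_stack([np.zeros((n, 2)), w]), limb,
                )
            )
        d["knee"], d["ankle_pt"], d["u_th"], d["u_sh"] = knee, ankle[limb], u_th, u_sh
        kin[limb] = d

    # total GRF from whole-body Newton-Euler
    acc_sum = m_hat * np.column_stack(
        [central_difference(hat_vel[:, 0], dt), central_difference(hat_vel[:, 1], dt)]
    )
    for limb in phases:
        for name in ("thigh", "shank", "foot"):
            acc_sum = acc_sum + kin[limb][name]["mass"] * kin[limb][name]["a"]
    F_tot = acc_sum - m * G_VEC[None, :2]  # = Σ m_i a_i + (0, m g)

    # per-limb split: smoothstep hand-off in double support, scaled by the
    # imposed loading asymmetry
    weight = {}
    rampw = (cfg.stance_fraction - 0.5) * T  # double-support duration, s
    for limb in phases:
        w = np.zeros(n)
        for t0 in starts[limb]:
            u = (t - t0) / ts
            up = _smoothstep((t - t0) / rampw)
            down = _smoothstep((t0 + ts - t) / rampw)
            mask = (u >= 0) & (u <= 1)
            w[mask] += np.minimum(up, down)[mask]
        weight[limb] = w
    weight["intact"] = cfg.load_share_asym * weight["intact"]
    denom = weight["intact"] + weight["prosthetic"]
    if np.any(denom <= 0):
        raise ValueError("flight phase: no limb assigned to carry load")
    grf = {}
    for limb in phases:
        frac = weight[limb] / denom
        grf[limb] = frac[:, None] * F_tot

    # COP: progresses heel to toe along the flat stance foot
    cop = {}
    for limb in phases:
        c = np.full((n, 2), np.nan)
        for t0 in starts[limb]:
            u = (t - t0) / ts
            mask = (u >= 0) & (u <= 1) & foot_on[limb]
            x_a = cfg.speed * (t0 + ts / 2)
            c[mask, 0] = x_a - 0.05 + 0.20 * _smoothstep(u[mask])
            c[mask, 1] = 0.0
        cop[limb] = c

    # bottom-up inverse dynamics per limb
    g2 = G_VEC[:2]
    joints_cols: dict[str, np.ndarray] = {}
    for limb in phases:
        d = kin[limb]
        F = grf[limb].copy()
        F[~foot_on[limb]] = 0.0
        cop_eff = np.where(np.isfinite(cop[limb]), cop[limb], d["ankle_pt"])
        ft, sh, th = d["foot"], d["shank"], d["thigh"]
        F_a = ft["mass"] * ft["a"] - ft["mass"] * g2[None, :] - F
        M_a = (
            ft["inertia"] * ft["alpha"]
            - _cross2(cop_eff - ft["p"], F)
            - _cross2(d["ankle_pt"] - ft["p"], F_a)
        )
        F_k = sh["mass"] * sh["a"] - sh["mass"] * g2[None, :] + F_a
        M_k = (
            sh["inertia"] * sh["alpha"]
            + _cross2(d["ankle_pt"] - sh["p"], F_a)
            + M_a
            - _cross2(d["knee"] - sh["p"], F_k)
        )
        F_h = th["mass"] * th["a"] - th["mass"] * g2[None, :] + F_k
        M_h = (
            th["inertia"] * th["alpha"]
            + _cross2(d["knee"] - th["p"], F_k)
            + M_k
            - _cross2(hip - th["p"], F_h)
        )
        joints_cols[f"{limb}_hip_moment"] = M_h
        joints_cols[f"{limb}_hip_ang_vel"] = th["w"]  # trunk does not rotate
        joints_cols[f"{limb}_hip_ab_moment"] = np.zeros(n)
        joints_cols[f"{limb}_hip_ab_ang_vel"] = np.zeros(n)
        joints_cols[f"{limb}_hip_rot_moment"] = np.zeros(n)
        joints_cols[f"{limb}_hip_rot_ang_vel"] = np.zeros(n)
        joints_cols[f"{limb}_knee_moment"] = M_k
        joints_cols[f"{limb}_knee_ang_vel"] = sh["w"] - th["w"]
        joints_cols[f"{limb}_ankle_moment"] = M_a
        joints_cols[f"{limb}_ankle_ang_vel"] = ft["w"] - sh["w"]

    # socket pistoning DOF (prosthetic thigh), with controlled hysteresis
    dissipated, stored, socket_windows = [], [], []
    if cfg.socket_compliance > 0:
        load = np.maximum(grf["prosthetic"][:, 1], 0.0)
        load[~foot_on["prosthetic"]] = 0.0
        disp = cfg.socket_compliance * load
        vel_d = central_difference(disp, dt)
        force = np.zeros(n)
        for t0 in starts["prosthetic"]:
            if t0 < 0 or t0 + ts > t[-1]:
                continue  # bookkeep only complete loading-unloading loops
            u = (t - t0) / ts
            mask = (u >= 0) & (u <= 1)
            if mask.sum() < 5:
                continue
            beta = _solve_hysteresis_beta(
                disp[mask], vel_d[mask], u[mask], t[mask],
                cfg.socket_compliance, cfg.socket_dissipation_frac,
            )
            f_win = disp[mask] / cfg.socket_compliance * (
                1.0 + beta * np.cos(np.pi * u[mask])
            )
            force[mask] = f_win
            p_sock = -f_win * vel_d[mask]
            pos_w = float(np.trapezoid(np.maximum(p_sock, 0.0), t[mask]))
            neg_w = float(np.trapezoid(np.minimum(p_sock, 0.0), t[mask]))
            dissipated.append(-(pos_w + neg_w))
            stored.append(-neg_w)
            idx = np.nonzero(mask)[0]
            socket_windows.append((int(idx[0]), int(idx[-1])))
        joints_cols["prosthetic_socket_piston_disp"] = disp
        joints_cols["prosthetic_socket_piston_vel"] = vel_d
        joints_cols["prosthetic_socket_piston_force"] = force

    com_acc = acc_sum / m
    grf_frames = {}
    for limb in phases:
        F = grf[limb].copy()
        F[~foot_on[limb]] = 0.0
        grf_frames[limb] = pd.DataFrame(
            {
                "fx": F[:, 0],
                "fy": F[:, 1],
                "fz": np.zeros(n),
                "copx": cop[limb][:, 0],
                "copy": cop[limb][:, 1],
                "copz": np.zeros(n),
            }
        )
    trial = GaitTrial(
        time=t,
        rate=fs,
        grf=grf_frames,
        segments=segments,
        joints=pd.DataFrame(joints_cols),
        body_mass=m,
        meta={
            "participant": cfg.participant,
            "interface": cfg.interface,
            "model": "planar_linkage",
        },
        extras={"com_acc": _to3(com_acc)},
    )
    truth = _ground_truth_from_trial(trial, cfg)
    truth.socket_dissipation = dissipated
    truth.socket_stored = stored
    truth.socket_windows = socket_windows
    return trial, truth


def _solve_hysteresis_beta(
    disp, vel_d, u, t_win, compliance, frac, iters: int = 4
) -> float:
    """Solve the loop-asymmetry coefficient so that the dissipated energy of
    the discrete force-displacement loop is exactly ``frac`` of the stored
    (absorbed) energy, both measured with the pipeline's trapezoidal
    quadrature on the emitted channels.

    The force path is F(u) = (δ(u)/c)·(1 + β cos(πu)): stiffer while loading,
    softer while unloading. Both dissipated (−net) and stored (−negative)
    work are piecewise-linear in β, so a few secant steps converge exactly.
    """
    if frac == 0:
        return 0.0

    def energies(beta):
        f = disp / compliance * (1.0 + beta * np.cos(np.pi * u))
        p = -f * vel_d
        pos = np.trapezoid(np.maximum(p, 0.0), t_win)
        neg = np.trapezoid(np.minimum(p, 0.0), t_win)
        return -(pos + neg), -neg  # dissipated, stored

    # analytic seed for a symmetric bump profile
    beta = 15.0 * frac / (16.0 - 8.0 * frac)
    b0, b1 = beta * 0.8, beta
    g0 = energies(b0)[0] - frac * energies(b0)[1]
    for _ in range(iters):
        g1 = energies(b1)[0] - frac * energies(b1)[1]
        if g1 == g0:
            break
        b0, b1, g0 = b1, b1 - g1 * (b1 - b0) / (g1 - g0), g1
    return b1


# ---------------------------------------------------------------------------
# measurement noise
# ---------------------------------------------------------------------------

def add_noise(
    trial: GaitTrial,
    noise_sd: dict | None = None,
    seed: int = 0,
    clamp_grf: bool = False,
) -> GaitTrial:
    """Additive i.i.d. Gaussian measurement noise, reproducible from ``seed``.

    ``noise_sd`` keys: ``force`` (N, GRF channels), ``kinematic`` (m, segment
    positions; velocity channels receive the matched differentiated-noise
    s.d. σ·rate/√2), ``moment`` (N·m, joint moment channels). sd 0 leaves the
    corresponding channels bit-identical. With ``clamp_grf`` the vGRF is
    clamped at 0 outside contact.
    """
    if noise_sd is None:
        noise_sd = {}
    for k, v in noise_sd.items():
        if v < 0:
            raise ValueError(f"noise sd for {k!r} must be >= 0")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 2718])
    out = copy.deepcopy(trial)
    s_f = noise_sd.get("force", 0.0)
    s_x = noise_sd.get("kinematic", 0.0)
    s_m = noise_sd.get("moment", 0.0)
    s_v = s_x * trial.rate / np.sqrt(2.0)
    for limb in out.limbs:
        if s_f:
            for col in ("fx", "fy", "fz"):
                noisy = out.grf[limb][col].to_numpy() + rng.normal(
                    0.0, s_f, len(out.time)
                )
                if clamp_grf and col == "fy":
                    contact = trial.vgrf(limb) > 0
                    noisy = np.where(contact, noisy, np.maximum(noisy, 0.0))
                out.grf[limb][col] = noisy
    if s_x:
        for seg in out.segments:
            seg.com_pos = seg.com_pos + rng.normal(0.0, s_x, seg.com_pos.shape)
            seg.com_vel = seg.com_vel + rng.normal(0.0, s_v, seg.com_vel.shape)
    if s_m and out.joints is not None:
        for col in out.joints.columns:
            if col.endswith("_moment"):
                out.joints[col] = out.joints[col].to_numpy() + rng.normal(
                    0.0, s_m, len(out.time)
                )
    return out
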