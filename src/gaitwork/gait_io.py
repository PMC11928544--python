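"""Reading and writing motion-capture text formats and pipeline outputs.

Supported formats
-----------------
* OpenSim-style storage files (``.mot`` / ``.sto``): tab-delimited, a free-form
  key=value header terminated by a line equal to ``endheader``, then a row of
  column names starting with ``time``.
* TRC marker files: the standard two-header-row marker layout; marker columns
  are expanded to ``<name>_x`` / ``_y`` / ``_z`` and converted to metres when
  the header declares millimetres.
* Generic CSV: first column ``time``, SI units assumed.

All series are held in a :class:`TimeSeries` (uniformly sampled, strictly
increasing time) and combined into a :class:`GaitTrial` for analysis.

Coordinate convention: right-handed lab frame, +X anterior (direction of
travel), +Y vertical up, +Z to the subject's right. Readers map file axes into
this frame via an axis-permutation mapping supplied by the caller.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "SegmentState",
    "GaitTrial",
    "FormatError",
    "read_storage",
    "write_storage",
    "write_summary",
    "read_summary",
    "assemble_trial",
]

GRAVITY = 9.81  # m s^-2, magnitude; gravity acts along -Y of the lab frame


class FormatError(ValueError):
    """A motion-capture file violates its declared layout."""


@dataclass
class TimeSeries:
    """Uniformly sampled, named channels on a strictly increasing time base.

    Parameters
    ----------
    time:
        Sample times in seconds, strictly increasing with a uniform step.
    data:
        One column per channel, ``len(data) == len(time)``.
    rate:
        Samples per second. If omitted, inferred from ``time``.
    """

    time: np.ndarray
    data: pd.DataFrame
    rate: float = 0.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("time base needs at least two samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        step = dt.mean()
        if np.any(np.abs(dt - step) > 1e-6 * max(step, 1.0)):
            raise ValueError("time step is not uniform")
        if len(self.data) != self.time.size:
            raise ValueError(
                f"channel rows ({len(self.data)}) != time samples ({self.time.size})"
            )
        if self.rate == 0.0:
            self.rate = 1.0 / step
        if abs(self.rate * step - 1.0) > 1e-6:
            raise ValueError("declared rate inconsistent with time step")

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return int(self.time.size)

    def channel(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def crop(self, t0: float, t1: float) -> "TimeSeries":
        """Restrict to samples with ``t0 <= time <= t1`` (inclusive, small slack)."""
        eps = 1e-9 / self.rate
        mask = (self.time >= t0 - eps) & (self.time <= t1 + eps)
        if mask.sum() < 2:
            raise ValueError("crop window contains fewer than two samples")
        return TimeSeries(self.time[mask], self.data.loc[mask].reset_index(drop=True))

    def resample(self, new_time: np.ndarray) -> "TimeSeries":
        """Linear interpolation onto ``new_time``; never extrapolates."""
        new_time = np.asarray(new_time, dtype=float)
        eps = 1e-9 / self.rate
        if new_time[0] < self.time[0] - eps or new_time[-1] > self.time[-1] + eps:
            raise ValueError("resample target extends beyond the source time range")
        if new_time.size == self.time.size and np.array_equal(new_time, self.time):
            return TimeSeries(self.time.copy(), self.data.copy())
        out = {
            c: np.interp(new_time, self.time, self.data[c].to_numpy())
            for c in self.data.columns
        }
        return TimeSeries(new_time, pd.DataFrame(out))


@dataclass
class SegmentState:
    """Rigid-segment state series used for peripheral (relative-to-COM) power.

    ``inertia`` is the 3x3 tensor about the segment COM, expressed in the frame
    in which ``ang_vel`` is given (for planar data: lab frame, spin about +Z).
    """

    name: str
    mass: float
    inertia: np.ndarray  # (3, 3)
    com_pos: np.ndarray  # (n, 3) m
    com_vel: np.ndarray  # (n, 3) m s^-1
    ang_vel: np.ndarray  # (n, 3) rad s^-1
    limb_assignment: str = "trunk"  # {left, right, trunk}

    def __post_init__(self) -> None:
        self.inertia = np.asarray(self.inertia, dtype=float)
        if self.mass < 0:
            raise ValueError(f"segment {self.name}: mass must be >= 0")
        if self.inertia.shape != (3, 3):
            raise ValueError(f"segment {self.name}: inertia must be 3x3")
        if not np.allclose(self.inertia, self.inertia.T, atol=1e-9):
            raise ValueError(f"segment {self.name}: inertia must be symmetric")
        eig = np.linalg.eigvalsh(self.inertia)
        if eig.min() < -1e-12:
            raise ValueError(f"segment {self.name}: inertia must be PSD")
        for attr in ("com_pos", "com_vel", "ang_vel"):
            arr = np.asarray(getattr(self, attr), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"segment {self.name}: {attr} must be (n, 3)")
            setattr(self, attr, arr)


@dataclass
class GaitTrial:
    """Time-synchronized forces, segment states, and joint channels of one trial.

    ``grf`` maps a limb label ({'left','right'} or {'prosthetic','intact'}) to a
    DataFrame with columns fx, fy, fz (N), mx, my, mz (N·m), copx, copy, copz (m);
    COP columns are NaN where the limb is unloaded. ``joints`` maps channel names
    (e.g. 'hip_r_flexion_moment') to series sharing the trial time base.
    """

    time: np.ndarray
    rate: float
    grf: dict[str, pd.DataFrame]
    segments: list[SegmentState] = field(default_factory=list)
    joints: pd.DataFrame | None = None
    body_mass: float = 0.0
    meta: dict = field(default_factory=dict)
    extras: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError("body_mass must be > 0")
        iface = self.meta.get("interface")
        if iface is not None and iface not in ("socket", "OI"):
            raise ValueError("interface label must be 'socket' or 'OI'")
        n = self.time.size
        for limb, df in self.grf.items():
            if len(df) != n:
                raise ValueError(f"GRF series for limb '{limb}' off the time base")
        if self.joints is not None and len(self.joints) != n:
            raise ValueError("joint channels off the time base")

    @property
    def limbs(self) -> list[str]:
        return list(self.grf)

    def vgrf(self, limb: str) -> np.ndarray:
        return self.grf[limb]["fy"].to_numpy()


# ---------------------------------------------------------------------------
# storage (.mot / .sto) files
# ---------------------------------------------------------------------------

def _read_text(path) -> list[str]:
    return Path(path).read_text(encoding="utf-8").splitlines()


def _parse_storage(lines: list[str], path) -> TimeSeries:
    header: dict[str, str] = {}
    i = 0
    for i, line in enumerate(lines):
        if line.strip() == "endheader":
            break
        if "=" in line:
            key, _, val = line.partition("=")
            header[key.strip()] = val.strip()
    else:
        raise FormatError(f"{path}: no 'endheader' line found")
    body = [ln for ln in lines[i + 1 :] if ln.strip()]
    if not body:
        raise FormatError(f"{path}: no column-name row after endheader")
    names = body[0].split("\t")
    names = [n.strip() for n in names if n.strip()]
    if not names or names[0].lower() != "time":
        raise FormatError(f"{path}: first column must be 'time', got {names[:1]}")
    ncol_decl = header.get("nColumns")
    if ncol_decl is not None and int(ncol_decl) != len(names):
        raise FormatError(
            f"{path}: header declares nColumns={ncol_decl} but found {len(names)}"
        )
    rows = []
    for r, ln in enumerate(body[1:]):
        vals = ln.split("\t")
        vals = [v for v in (x.strip() for x in vals) if v != ""]
        if len(vals) != len(names):
            raise FormatError(
                f"{path}: row {r} has {len(vals)} fields, expected {len(names)}"
            )
        rows.append([float(v) for v in vals])
    nrow_decl = header.get("nRows")
    if nrow_decl is not None and int(nrow_decl) != len(rows):
        raise FormatError(
            f"{path}: header declares nRows={nrow_decl} but found {len(rows)}"
        )
    arr = np.array(rows, dtype=float)
    return TimeSeries(arr[:, 0], pd.DataFrame(arr[:, 1:], columns=names[1:]))


def _parse_trc(lines: list[str], path) -> TimeSeries:
    # line 0: PathFileType...; line 1: meta keys; line 2: meta values;
    # line 3: Frame#  Time  Marker1 .. ; line 4: X1 Y1 Z1 ...
    if len(lines) < 6:
        raise FormatError(f"{path}: truncated TRC file")
    keys = lines[1].split("\t")
    vals = lines[2].split("\t")
    meta = dict(zip((k.strip() for k in keys), (v.strip() for v in vals)))
    units = meta.get("Units", "mm")
    scale = 1e-3 if units.lower() == "mm" else 1.0
    marker_row = lines[3].split("\t")
    markers = [m.strip() for m in marker_row[2:] if m.strip()]
    n_markers_decl = meta.get("NumMarkers")
    if n_markers_decl is not None and int(n_markers_decl) != len(markers):
        raise FormatError(
            f"{path}: NumMarkers={n_markers_decl} but header row lists {len(markers)}"
        )
    names = []
    for m in markers:
        names += [f"{m}_x", f"{m}_y", f"{m}_z"]
    rows, times = [], []
    for r, ln in enumerate(lines[5:]):
        if not ln.strip():
            continue
        fields = [f for f in ln.split("\t")]
        fields = [f.strip() for f in fields]
        fields = [f for f in fields if f != ""]
        if len(fields) != 2 + 3 * len(markers):
            raise FormatError(
                f"{path}: data row {r} has {len(fields)} fields, "
                f"expected {2 + 3 * len(markers)}"
            )
        times.append(float(fields[1]))
        rows.append([float(v) * scale for v in fields[2:]])
    arr = np.array(rows, dtype=float)
    return TimeSeries(np.array(times), pd.DataFrame(arr, columns=names))


def _parse_csv(path) -> TimeSeries:
    df = pd.read_csv(path)
    if df.columns[0].lower() != "time":
        raise FormatError(f"{path}: CSV first column must be 'time'")
    return TimeSeries(
        df.iloc[:, 0].to_numpy(dtype=float), df.iloc[:, 1:].astype(float)
    )


def read_storage(path, kind: str | None = None) -> TimeSeries:
    """Read a MOT/STO/TRC/CSV file into a :class:`TimeSeries`.

    ``kind`` defaults to the file extension. TRC marker columns are expanded to
    ``<name>_x/_y/_z`` and converted to metres when the header declares mm.
    """
    path = Path(path)
    if kind is None:
        kind = path.suffix.lstrip(".").lower()
    kind = kind.lower()
    if kind in ("mot", "sto"):
        return _parse_storage(_read_text(path), path)
    if kind == "trc":
        return _parse_trc(_read_text(path), path)
    if kind == "csv":
        return _parse_csv(path)
    raise ValueError(f"unsupported storage kind: {kind!r}")


def write_storage(ts: TimeSeries, path) -> None:
    """Write a TimeSeries as a tab-delimited .sto/.mot storage file."""
    path = Path(path)
    names = ["time"] + ts.channels
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{path.stem}\nversion=1\n")
        fh.write(f"nRows={len(ts)}\nnColumns={len(names)}\n")
        fh.write("inDegrees=no\nendheader\n")
        fh.write("\t".join(names) + "\n")
        mat = np.column_stack([ts.time] + [ts.channel(c) for c in ts.channels])
        for row in mat:
            fh.write("\t".join(format(v, ".12g") for v in row) + "\n")


# ---------------------------------------------------------------------------
# summary outputs
# ---------------------------------------------------------------------------

_SUMMARY_COLUMNS = [
    "participant",
    "interface",
    "limb",
    "source",
    "speed",
    "speed_bin",
    "stride",
    "net",
    "positive",
    "negative",
]


def write_summary(results: Iterable[Mapping], path) -> None:
    """Write per-stride work summaries as CSV with a deterministic column order.

    Each element supplies at least the net/positive/negative work fields; NaN
    values round-trip as the explicit token ``NaN``.
    """
    rows = [dict(r) for r in results]
    if not rows:
        raise ValueError("cannot write an empty summary collection")
    df = pd.DataFrame(rows)
    ordered = [c for c in _SUMMARY_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in _SUMMARY_COLUMNS
    ]
    df = df[ordered]
    df.to_csv(path, index=False, na_rep="NaN", float_format="%.17g")


def read_summary(path) -> pd.DataFrame:
    """Read back a summary CSV written by :func:`write_summary`."""
    return pd.read_csv(path, na_values=["NaN"])


def write_ground_truth(truth: Mapping, path) -> None:
    """Serialize a generator ground-truth mapping to JSON (lists for arrays)."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(truth, indent=1, default=default), "utf-8")


# ---------------------------------------------------------------------------
# trial assembly
# ---------------------------------------------------------------------------

def assemble_trial(
    force_ts: Mapping[str, TimeSeries],
    kinematic_ts: TimeSeries,
    joint_ts: TimeSeries | None,
    meta: Mapping,
    *,
    segments: Sequence[SegmentState] = (),
) -> GaitTrial:
    """Crop all series to their common time window and resample to the
    kinematic rate by linear interpolation.

    ``force_ts`` maps limb labels to TimeSeries whose channels include
    fx/fy/fz (and optionally mx/my/mz, copx/copy/copz). ``meta`` must carry
    ``body_mass``; ``interface`` and ``participant`` are passed through.
    """
    all_ts = list(force_ts.values()) + [kinematic_ts]
    if joint_ts is not None:
        all_ts.append(joint_ts)
    t0 = max(ts.time[0] for ts in all_ts)
    t1 = min(ts.time[-1] for ts in all_ts)
    if t1 <= t0:
        raise ValueError("series time ranges are disjoint")
    kin = kinematic_ts.crop(t0, t1)
    base = kin.time
    grf = {}
    for limb, ts in force_ts.items():
        rs = ts.resample(base)
        df = rs.data
        for col in ("fx", "fy", "fz"):
            if col not in df.columns:
                raise ValueError(f"force series for '{limb}' lacks channel {col}")
        grf[limb] = df
    joints = joint_ts.resample(base).data if joint_ts is not None else None
    return GaitTrial(
        time=base,
        rate=kin.rate,
        grf=grf,
        segments=list(segments),
        joints=joints,
        body_mass=float(meta["body_mass"]),
        meta=dict(meta),
    )
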