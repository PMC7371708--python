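"""Reading, validation and preprocessing of hourly GPS trajectories.

The sampling unit throughout the package is the *animal-year*: one
individual's trajectory within one winter experiment. An experiment is
split into three contiguous phases (pre-closure, closure, post-closure)
whose raw durations differ between animal-years; for comparability every
phase is truncated to a common 14-day window before any analysis.

Coordinates are projected meters (easting/northing); timestamps are UTC
and nominally hourly. Missing fixes are never interpolated: steps that
span a gap are flagged and excluded from turning-angle and lag chains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "Trajectory",
    "PhaseSchedule",
    "TrajectoryError",
    "read_fixes",
    "write_fixes",
    "read_schedules",
    "write_schedules",
    "detect_resettlement",
    "truncate_phases",
    "compute_steps",
    "transform_movement",
    "lag_features",
    "population_mean_step",
]

#: Phase labels in experimental order.
PHASES = ("pre", "closure", "post")

#: Default clamp for logit transforms (turning angles, overlap statistics).
LOGIT_EPS = 1e-6

#: Floor (meters) applied before taking log step length.
LOG_STEP_FLOOR = 1.0

NOMINAL_INTERVAL = pd.Timedelta(hours=1)


class TrajectoryError(ValueError):
    """Malformed trajectory input or an unusable animal-year."""


@dataclass
class Trajectory:
    """Ordered hourly fixes for one animal-year.

    ``fixes`` holds columns ``timestamp`` (UTC), ``x``, ``y`` and, after
    :func:`truncate_phases`, a categorical ``phase`` column.
    """

    animal_year_id: str
    animal_id: str
    sex: str
    year: int
    fixes: pd.DataFrame
    nominal_interval: pd.Timedelta = field(default=NOMINAL_INTERVAL)

    def __post_init__(self) -> None:
        f = self.fixes
        if len(f) < 2:
            raise TrajectoryError(
                f"{self.animal_year_id}: a trajectory needs >= 2 fixes"
            )
        if not f["timestamp"].is_monotonic_increasing or f["timestamp"].duplicated().any():
            dup = f.loc[f["timestamp"].duplicated(), "timestamp"]
            raise TrajectoryError(
                f"{self.animal_year_id}: timestamps must be strictly increasing"
                + (f" (duplicate at {dup.iloc[0]})" if len(dup) else "")
            )
        if not np.isfinite(f[["x", "y"]].to_numpy()).all():
            raise TrajectoryError(f"{self.animal_year_id}: non-finite coordinates")
        gaps = f["timestamp"].diff().dropna()
        rem = (gaps / self.nominal_interval) % 1
        if not np.allclose(rem.astype(float), 0.0):
            raise TrajectoryError(
                f"{self.animal_year_id}: inter-fix gaps must be integer multiples "
                f"of {self.nominal_interval}"
            )
        if self.sex not in ("F", "M"):
            raise TrajectoryError(f"{self.animal_year_id}: unknown sex code {self.sex!r}")

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    def with_fixes(self, fixes: pd.DataFrame) -> "Trajectory":
        obj = replace(self, fixes=fixes.reset_index(drop=True))
        return obj


@dataclass(frozen=True)
class PhaseSchedule:
    """Experimental phase boundaries for one animal-year.

    Boundaries are half-open: pre-closure is ``[pre_start, closure_start)``,
    closure ``[closure_start, post_start)``, post-closure
    ``[post_start, post_end)``.
    """

    animal_year_id: str
    pre_start: pd.Timestamp
    closure_start: pd.Timestamp
    post_start: pd.Timestamp
    post_end: pd.Timestamp
    capture_location: tuple[float, float] | None = None
    manipulated_site_id: str | None = None

    def __post_init__(self) -> None:
        ts = (self.pre_start, self.closure_start, self.post_start, self.post_end)
        if not all(a < b for a, b in zip(ts, ts[1:])):
            raise TrajectoryError(
                f"{self.animal_year_id}: phase boundaries must be strictly ordered"
            )

    def raw_length(self, phase: str) -> pd.Timedelta:
        starts = {
            "pre": (self.pre_start, self.closure_start),
            "closure": (self.closure_start, self.post_start),
            "post": (self.post_start, self.post_end),
        }
        a, b = starts[phase]
        return b - a


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

FIXES_COLUMNS = ["animal_year_id", "animal_id", "sex", "timestamp", "x", "y"]
SCHEDULE_COLUMNS = [
    "animal_year_id", "pre_start", "closure_start", "post_start", "post_end",
    "capture_x", "capture_y", "manipulated_site_id",
]


def read_fixes(path: str | Path) -> list[Trajectory]:
    """Read a fixes CSV into per-animal-year trajectories.

    The file schema is ``animal_year_id,animal_id,sex,timestamp,x,y`` with
    ISO-8601 UTC timestamps and projected-meter coordinates. Trajectories
    are returned sorted by animal-year id; rows within an animal-year are
    sorted by time. Duplicate timestamps or unknown sex codes raise
    :class:`TrajectoryError` naming the offending animal-year.
    """
    df = pd.read_csv(path)
    missing = [c for c in FIXES_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryError(f"{path}: missing columns {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    out: list[Trajectory] = []
    for ay_id, grp in df.groupby("animal_year_id", sort=True):
        grp = grp.sort_values("timestamp").reset_index(drop=True)
        meta = grp.iloc[0]
        year = int(pd.Timestamp(meta["timestamp"]).year)
        out.append(
            Trajectory(
                animal_year_id=str(ay_id),
                animal_id=str(meta["animal_id"]),
                sex=str(meta["sex"]),
                year=year,
                fixes=grp[["timestamp", "x", "y"]].copy(),
            )
        )
    return out


def write_fixes(trajs: Iterable[Trajectory], path: str | Path) -> None:
    rows = []
    for t in trajs:
        f = t.fixes
        rows.append(
            pd.DataFrame(
                {
                    "animal_year_id": t.animal_year_id,
                    "animal_id": t.animal_id,
                    "sex": t.sex,
                    "timestamp": f["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ"),
                    "x": f["x"],
                    "y": f["y"],
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_schedules(path: str | Path) -> dict[str, PhaseSchedule]:
    df = pd.read_csv(path)
    out: dict[str, PhaseSchedule] = {}
    for _, r in df.iterrows():
        cap = None
        if "capture_x" in df.columns and pd.notna(r.get("capture_x")):
            cap = (float(r["capture_x"]), float(r["capture_y"]))
        msid = r.get("manipulated_site_id")
        out[str(r["animal_year_id"])] = PhaseSchedule(
            animal_year_id=str(r["animal_year_id"]),
            pre_start=pd.Timestamp(r["pre_start"], tz="UTC"),
            closure_start=pd.Timestamp(r["closure_start"], tz="UTC"),
            post_start=pd.Timestamp(r["post_start"], tz="UTC"),
            post_end=pd.Timestamp(r["post_end"], tz="UTC"),
            capture_location=cap,
            manipulated_site_id=None if pd.isna(msid) else str(msid),
        )
    return out


def write_schedules(schedules: Iterable[PhaseSchedule], path: str | Path) -> None:
    fmt = "%Y-%m-%dT%H:%M:%SZ"
    rows = []
    for s in schedules:
        rows.append(
            {
                "animal_year_id": s.animal_year_id,
                "pre_start": s.pre_start.strftime(fmt),
                "closure_start": s.closure_start.strftime(fmt),
                "post_start": s.post_start.strftime(fmt),
                "post_end": s.post_end.strftime(fmt),
                "capture_x": s.capture_location[0] if s.capture_location else "",
                "capture_y": s.capture_location[1] if s.capture_location else "",
                "manipulated_site_id": s.manipulated_site_id or "",
            }
        )
    pd.DataFrame(rows, columns=SCHEDULE_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Resettlement and phase truncation
# ---------------------------------------------------------------------------

def detect_resettlement(
    traj: Trajectory, capture_location: tuple[float, float], radius: float
) -> pd.Timestamp:
    """Timestamp of the first return to the capture location.

    Animals show a post-capture flight response; the first re-visitation of
    the capture location (first fix inside ``radius`` after having left it)
    marks resettlement in the original range and is used as the pre-closure
    onset. A trajectory that never leaves the radius resettles immediately
    (first fix time); one that never returns raises :class:`TrajectoryError`
    (the animal-year is unusable).
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    cx, cy = capture_location
    d = np.hypot(traj.fixes["x"] - cx, traj.fixes["y"] - cy).to_numpy()
    inside = d <= radius
    if inside.all():
        return traj.fixes["timestamp"].iloc[0]
    first_out = int(np.argmax(~inside))
    back = np.nonzero(inside[first_out:])[0]
    if back.size == 0:
        raise TrajectoryError(
            f"{traj.animal_year_id}: no re-visitation of the capture location"
        )
    return traj.fixes["timestamp"].iloc[first_out + int(back[0])]


def truncate_phases(
    traj: Trajectory,
    schedule: PhaseSchedule,
    target: pd.Timedelta = pd.Timedelta(days=14),
) -> Trajectory:
    """Homogenize phase durations to a common window and label fixes.

    Pre-closure and closure keep their *final* ``target`` days (anchored at
    the end of the phase: initial excess positions are removed); post-closure
    keeps its *first* ``target`` days (terminal excess removed). Each
    retained fix carries a ``phase`` label. Raises if any raw phase is
    shorter than ``target``. Idempotent on already-truncated data.
    """
    for ph in PHASES:
        if schedule.raw_length(ph) < target:
            raise TrajectoryError(
                f"{traj.animal_year_id}: raw {ph} phase "
                f"({schedule.raw_length(ph)}) shorter than target {target}"
            )
    windows = {
        "pre": (schedule.closure_start - target, schedule.closure_start),
        "closure": (schedule.post_start - target, schedule.post_start),
        "post": (schedule.post_start, schedule.post_start + target),
    }
    ts = traj.fixes["timestamp"]
    label = pd.Series(pd.NA, index=traj.fixes.index, dtype="object")
    for ph, (a, b) in windows.items():
        label[(ts >= a) & (ts < b)] = ph
    kept = traj.fixes.loc[label.notna()].copy()
    kept["phase"] = pd.Categorical(label.dropna(), categories=list(PHASES))
    return traj.with_fixes(kept)


# ---------------------------------------------------------------------------
# Steps, turning angles, transforms, lags
# ---------------------------------------------------------------------------

def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi], counterclockwise positive."""
    w = np.mod(a + np.pi, 2 * np.pi) - np.pi
    return np.where(w == -np.pi, np.pi, w)


def compute_steps(traj: Trajectory) -> pd.DataFrame:
    """Step lengths and turning angles of an hourly trajectory.

    Returns one row per step (``n_fixes - 1`` rows) with columns:

    ``t_end``
        timestamp of the step's end fix (steps are attributed to the hour
        they end in, so lagged covariates align on end times);
    ``step``
        Euclidean length s_t in meters;
    ``turn``
        signed turning angle between this step's heading and the previous
        step's heading, wrapped to (-pi, pi], counterclockwise positive;
        NaN for the first step, at gap junctions and where the heading is
        undefined;
    ``phase``
        phase label of the end fix when the input is phase-labelled, and
        NaN for steps that straddle a phase boundary's missing fix;
    ``gap``
        True when the step spans more than the nominal interval (such steps
        are excluded from turn and lag chains, and their length is never
        synthesized across the gap).

    Zero-length steps have no heading of their own; the previous non-zero
    heading is carried forward so the next turning angle stays defined.
    """
    f = traj.fixes
    ts = f["timestamp"].to_numpy()
    x = f["x"].to_numpy(dtype=float)
    y = f["y"].to_numpy(dtype=float)
    dx = np.diff(x)
    dy = np.diff(y)
    step = np.hypot(dx, dy)
    dt = f["timestamp"].diff().iloc[1:]
    gap = (dt > traj.nominal_interval).to_numpy()

    heading = np.where(step > 0, np.arctan2(dy, dx), np.nan)
    # carry heading over zero-length steps
    eff = heading.copy()
    for i in range(1, len(eff)):
        if np.isnan(eff[i]) and step[i] == 0:
            eff[i] = eff[i - 1]
    turn = np.full(len(step), np.nan)
    if len(step) >= 2:
        turn[1:] = _wrap_angle(heading[1:] - eff[:-1])
        # a turn is undefined when either bounding step spans a gap
        turn[1:][gap[1:] | gap[:-1]] = np.nan
        turn[1:][np.isnan(eff[:-1]) | np.isnan(heading[1:])] = np.nan
    out = pd.DataFrame(
        {
            "animal_year_id": traj.animal_year_id,
            "t_end": f["timestamp"].iloc[1:].to_numpy(),
            "step": step,
            "turn": turn,
            "gap": gap,
        }
    )
    if "phase" in f.columns:
        start_ph = f["phase"].iloc[:-1].to_numpy()
        end_ph = f["phase"].iloc[1:].to_numpy()
        same = (start_ph == end_ph) & ~gap
        out["phase"] = pd.Categorical(
            np.where(same, end_ph, None), categories=list(PHASES)
        )
    return out


def transform_movement(
    steps: pd.DataFrame, eps: float = LOGIT_EPS, s_min: float = LOG_STEP_FLOOR
) -> pd.DataFrame:
    """Attach modelling transforms: log step length and logit turning angle.

    ``log_step`` = ln(max(s_t, s_min)).  ``phi`` is the logit of the
    absolute turning angle expressed as a fraction of pi, clamped to
    [eps, 1 - eps] so the transform is total: since turning angles live on
    (-pi, pi], |theta|/pi is the only linear scaling onto (0, 1).
    """
    if not 0 < eps < 0.5:
        raise ValueError("eps must be in (0, 0.5)")
    out = steps.copy()
    out["log_step"] = np.log(np.maximum(out["step"], s_min))
    frac = np.clip(np.abs(out["turn"]) / np.pi, eps, 1 - eps)
    out["phi"] = np.log(frac / (1 - frac))
    return out


def lag_features(
    steps: pd.DataFrame,
    columns: Sequence[str] = ("log_step",),
    lags: Sequence[int] = (1, 2, 24),
) -> pd.DataFrame:
    """Attach lagged copies of step covariates on the hourly slot grid.

    For each requested column c and lag k a column ``c_lag{k}`` holds the
    value k hours before the step's end time; slots with no fix (GPS gaps)
    yield missing lags. Rows with missing lags stay in the frame — model
    tables drop them (never impute) and report the count.
    """
    out = []
    for _, grp in steps.groupby("animal_year_id", sort=False, observed=True):
        g = grp.copy()
        t0 = g["t_end"].iloc[0]
        slot = ((g["t_end"] - t0) / NOMINAL_INTERVAL).round().astype(int)
        idx = pd.Index(slot, name="slot")
        for c in columns:
            ser = pd.Series(g[c].to_numpy(), index=idx)
            # a step that spans a gap has no well-defined hourly value
            ser[g["gap"].to_numpy()] = np.nan
            full = ser.reindex(range(int(slot.max()) + 1))
            for k in lags:
                g[f"{c}_lag{k}"] = full.shift(k).reindex(idx).to_numpy()
        out.append(g)
    return pd.concat(out, ignore_index=True)


def population_mean_step(step_tables: Iterable[pd.DataFrame]) -> float:
    """Population mean hourly displacement l over all retained 1-h steps.

    This scale parameter sets the feeding-site buffer radius and, halved,
    the kernel bandwidth of the utilization distributions.
    """
    vals = [t.loc[~t["gap"], "step"] for t in step_tables]
    allv = pd.concat(vals, ignore_index=True)
    if allv.empty:
        raise TrajectoryError("no steps available to compute l")
    return float(allv.mean())
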