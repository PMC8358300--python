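"""Force-plate ingestion and center-of-pressure (COP) trajectory handling.

A force plate reports three forces (fx, fy, fz) and three moments
(mx, my, mz) about its sensor origin.  The COP is the point on the plate
surface where the ground-reaction force acts; for a sensor origin a
vertical distance ``h`` below the surface the plate-frame coordinates are

    cop_x = (-my - fx * h) / fz
    cop_y = ( mx - fy * h) / fz

An :class:`AxisMap` then declares which plate axis carries anteroposterior
(AP) sway and which mediolateral (ML), with signs.  The default maps
AP to plate x and ML to plate y, both positive, matching a plate whose
x axis points anteriorly when the participant faces +x.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ConfigError, StructuralError, UnloadedPlateError

#: maximum tolerated jitter of the time base, seconds
TIME_JITTER_S = 1e-6

#: default minimum |fz| (newtons) below which the plate counts as unloaded
DEFAULT_FZ_THRESHOLD_N = 10.0


@dataclass(frozen=True)
class AxisMap:
    """Declaration of which plate axis is AP and which is ML.

    ``ap`` / ``ml`` name the plate axis ("x" or "y"); the signs flip the
    series so that anterior and left are positive under the lab convention.
    """

    ap: str = "x"
    ml: str = "y"
    ap_sign: int = 1
    ml_sign: int = 1

    def __post_init__(self):
        if {self.ap, self.ml} != {"x", "y"}:
            raise ConfigError(
                f"axis_map must assign 'x' and 'y' to AP and ML, got "
                f"ap={self.ap!r}, ml={self.ml!r}"
            )
        if self.ap_sign not in (-1, 1) or self.ml_sign not in (-1, 1):
            raise ConfigError("axis signs must be +1 or -1")


@dataclass
class ForcePlateRecording:
    """Raw force/moment channels with sampling metadata.

    Forces in newtons, moments in newton-meters, time in seconds.
    ``plate_origin_offset_h`` is the vertical distance (m) from the plate
    surface to the sensor origin (AMTI-class plates measure moments about
    a sub-surface origin).
    """

    time: np.ndarray
    fx: np.ndarray
    fy: np.ndarray
    fz: np.ndarray
    mx: np.ndarray
    my: np.ndarray
    mz: np.ndarray
    sampling_rate: float
    plate_origin_offset_h: float = 0.0
    axis_map: AxisMap = field(default_factory=AxisMap)

    def __post_init__(self):
        arrays = {}
        for name in ("time", "fx", "fy", "fz", "mx", "my", "mz"):
            arrays[name] = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arrays[name])
        n = len(self.time)
        if n < 2:
            raise StructuralError("recording needs at least 2 samples")
        for name, arr in arrays.items():
            if arr.ndim != 1 or len(arr) != n:
                raise StructuralError(
                    f"channel {name!r} length {arr.size} != time length {n}"
                )
        if not self.sampling_rate > 0:
            raise StructuralError("sampling_rate must be positive")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise StructuralError("time must be strictly increasing")
        if np.max(np.abs(dt - 1.0 / self.sampling_rate)) > TIME_JITTER_S:
            raise StructuralError(
                "time base not uniform at the declared sampling rate "
                f"(max deviation {np.max(np.abs(dt - 1.0 / self.sampling_rate)):.2e} s)"
            )

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        return (self.n_samples - 1) / self.sampling_rate


@dataclass
class COPTrajectory:
    """Centered or raw 2-D COP path for one trial, in millimeters."""

    ap: np.ndarray
    ml: np.ndarray
    sampling_rate: float
    centered: bool = False
    label: tuple | None = None  # optional (condition, trial) tag

    def __post_init__(self):
        self.ap = np.asarray(self.ap, dtype=float)
        self.ml = np.asarray(self.ml, dtype=float)
        if self.ap.ndim != 1 or self.ml.ndim != 1:
            raise StructuralError("ap and ml must be 1-D series")
        if len(self.ap) != len(self.ml):
            raise StructuralError(
                f"ap length {len(self.ap)} != ml length {len(self.ml)}"
            )
        if len(self.ap) == 0:
            raise StructuralError("empty trajectory")
        if not self.sampling_rate > 0:
            raise StructuralError("sampling_rate must be positive")
        if self.centered:
            for name, arr in (("ap", self.ap), ("ml", self.ml)):
                if abs(arr.mean()) > 1e-9:
                    raise StructuralError(
                        f"trajectory marked centered but mean({name}) = "
                        f"{arr.mean():.3g} mm"
                    )

    @property
    def n_samples(self) -> int:
        return len(self.ap)

    @property
    def duration(self) -> float:
        """Elapsed time (s) between first and last sample."""
        return (self.n_samples - 1) / self.sampling_rate


@dataclass(frozen=True)
class TrialSchedule:
    """Timing of the recording protocol.

    Defaults reflect a six-condition sensory-organization protocol with
    three 20-s quiet-standing trials per condition and 5-s breaks.
    """

    n_conditions: int = 6
    trials_per_condition: int = 3
    trial_duration: float = 20.0
    inter_trial_break: float = 5.0

    def __post_init__(self):
        for name in ("n_conditions", "trials_per_condition"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("trial_duration", "inter_trial_break"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")

    @property
    def condition_duration(self) -> float:
        """Span of one condition block: trials plus the breaks between them."""
        k = self.trials_per_condition
        return k * self.trial_duration + (k - 1) * self.inter_trial_break

    @property
    def total_duration(self) -> float:
        """Full schedule span, with an inter-condition break equal to the
        inter-trial break."""
        c = self.n_conditions
        return c * self.condition_duration + (c - 1) * self.inter_trial_break

    def trial_starts(self) -> list[tuple[int, int, float]]:
        """(condition, trial, start_time_s) for every trial, 1-based labels."""
        out = []
        for c in range(self.n_conditions):
            c_start = c * (self.condition_duration + self.inter_trial_break)
            for t in range(self.trials_per_condition):
                out.append(
                    (c + 1, t + 1,
                     c_start + t * (self.trial_duration + self.inter_trial_break))
                )
        return out


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase low-pass configuration (Butterworth, filtfilt)."""

    cutoff_hz: float
    order: int = 4

    def __post_init__(self):
        if not self.cutoff_hz > 0:
            raise ConfigError("cutoff_hz must be positive")
        if self.order < 1:
            raise ConfigError("filter order must be >= 1")


def compute_cop(
    rec: ForcePlateRecording,
    fz_threshold: float = DEFAULT_FZ_THRESHOLD_N,
) -> COPTrajectory:
    """Derive the COP path (mm, uncentered) from force-plate channels.

    Raises :class:`UnloadedPlateError` naming the first sample where
    ``|fz|`` falls at or below ``fz_threshold``.
    """
    bad = np.flatnonzero(np.abs(rec.fz) <= fz_threshold)
    if bad.size:
        raise UnloadedPlateError(int(bad[0]), float(rec.fz[bad[0]]), fz_threshold)
    h = rec.plate_origin_offset_h
    cop_x = (-rec.my - rec.fx * h) / rec.fz  # meters, plate frame
    cop_y = (rec.mx - rec.fy * h) / rec.fz
    plate = {"x": cop_x, "y": cop_y}
    amap = rec.axis_map
    ap = amap.ap_sign * plate[amap.ap] * 1000.0  # -> mm
    ml = amap.ml_sign * plate[amap.ml] * 1000.0
    return COPTrajectory(ap=ap, ml=ml, sampling_rate=rec.sampling_rate,
                         centered=False)


def center_trajectory(traj: COPTrajectory) -> COPTrajectory:
    """Remove the per-axis mean; idempotent."""
    ap = traj.ap - traj.ap.mean()
    ml = traj.ml - traj.ml.mean()
    return COPTrajectory(ap=ap, ml=ml, sampling_rate=traj.sampling_rate,
                         centered=True, label=traj.label)


def preprocess(
    traj: COPTrajectory, filter_spec: FilterSpec | None = None
) -> COPTrajectory:
    """Optional zero-phase low-pass, then centering.

    The default is no filter, so the output equals
    ``center_trajectory(traj)``.
    """
    if filter_spec is None:
        return center_trajectory(traj)
    nyquist = traj.sampling_rate / 2.0
    if filter_spec.cutoff_hz >= nyquist:
        raise ConfigError(
            f"low-pass cutoff {filter_spec.cutoff_hz:g} Hz must be below "
            f"the Nyquist frequency {nyquist:g} Hz"
        )
    sos = signal.butter(
        filter_spec.order, filter_spec.cutoff_hz, btype="low",
        fs=traj.sampling_rate, output="sos",
    )
    ap = signal.sosfiltfilt(sos, traj.ap)
    ml = signal.sosfiltfilt(sos, traj.ml)
    return center_trajectory(
        COPTrajectory(ap=ap, ml=ml, sampling_rate=traj.sampling_rate,
                      label=traj.label)
    )


def segment_trials(
    data: COPTrajectory | ForcePlateRecording,
    schedule: TrialSchedule | None = None,
    start_times: Sequence[float] | None = None,
) -> list[COPTrajectory]:
    """Cut a continuous recording into labeled per-trial trajectories.

    Windows are half-open ``[t0, t0 + trial_duration)`` at integer sample
    boundaries, so each 20-s trial at 200 Hz has exactly 4000 samples and
    adjacent trials never share a boundary sample.  Labels enumerate
    ``(condition, trial)`` starting at (1, 1), condition-major.

    ``start_times`` overrides the schedule's computed trial onsets (it must
    then list one onset per trial, in schedule order).
    """
    if schedule is None:
        schedule = TrialSchedule()
    if isinstance(data, ForcePlateRecording):
        traj = compute_cop(data)
    else:
        traj = data
    fs = traj.sampling_rate
    n_per_trial = round(schedule.trial_duration * fs)

    if start_times is not None:
        starts = [(None, None, float(t)) for t in sorted(start_times)]
        for (_, _, a), (_, _, b) in zip(starts, starts[1:]):
            if b < a + schedule.trial_duration:
                raise StructuralError(
                    f"overlapping trial windows: start {b:g} s < "
                    f"{a:g} s + {schedule.trial_duration:g} s"
                )
        labels = [(c, t) for c, t, _ in TrialSchedule(
            n_conditions=max(1, (len(starts) + schedule.trials_per_condition - 1)
                             // schedule.trials_per_condition),
            trials_per_condition=schedule.trials_per_condition,
            trial_duration=schedule.trial_duration,
            inter_trial_break=schedule.inter_trial_break,
        ).trial_starts()][: len(starts)]
        entries = [(lab, s) for lab, (_, _, s) in zip(labels, starts)]
    else:
        need = schedule.total_duration
        have = traj.n_samples / fs
        if have + 0.5 / fs < need:
            raise StructuralError(
                f"recording too short for schedule: need {need:g} s, "
                f"have {have:g} s"
            )
        entries = [((c, t), s) for c, t, s in schedule.trial_starts()]

    out = []
    for (cond, trial), t0 in entries:
        i0 = round(t0 * fs)
        i1 = i0 + n_per_trial
        if i1 > traj.n_samples:
            raise StructuralError(
                f"trial starting at {t0:g} s needs samples up to index {i1}, "
                f"recording has {traj.n_samples}"
            )
        out.append(
            COPTrajectory(
                ap=traj.ap[i0:i1].copy(), ml=traj.ml[i0:i1].copy(),
                sampling_rate=fs, centered=False, label=(cond, trial),
            )
        )
    return out


# ---------------------------------------------------------------------------
# CSV I/O

_FORCE_COLS = ["time", "fx", "fy", "fz", "mx", "my", "mz"]


def read_force_csv(
    path: str | Path,
    sampling_rate: float | None = None,
    plate_origin_offset_h: float = 0.0,
    axis_map: AxisMap | None = None,
) -> ForcePlateRecording:
    """Read a force CSV with header columns time,fx,fy,fz,mx,my,mz (SI units).

    Comma or tab delimited (sniffed).  If ``sampling_rate`` is omitted it is
    inferred from the median time step.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _FORCE_COLS if c not in df.columns]
    if missing:
        raise StructuralError(f"force CSV {path} missing columns {missing}")
    if sampling_rate is None:
        dt = np.median(np.diff(df["time"].to_numpy()))
        if dt <= 0:
            raise StructuralError("cannot infer sampling rate: bad time column")
        sampling_rate = 1.0 / dt
    return ForcePlateRecording(
        time=df["time"].to_numpy(),
        fx=df["fx"].to_numpy(), fy=df["fy"].to_numpy(), fz=df["fz"].to_numpy(),
        mx=df["mx"].to_numpy(), my=df["my"].to_numpy(), mz=df["mz"].to_numpy(),
        sampling_rate=float(sampling_rate),
        plate_origin_offset_h=plate_origin_offset_h,
        axis_map=axis_map or AxisMap(),
    )


def read_cop_csv(path: str | Path, sampling_rate: float | None = None) -> COPTrajectory:
    """Read a COP CSV with columns time_s,cop_ap_mm,cop_ml_mm."""
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("time_s", "cop_ap_mm", "cop_ml_mm"):
        if col not in df.columns:
            raise StructuralError(f"COP CSV {path} missing column {col!r}")
    if sampling_rate is None:
        dt = np.median(np.diff(df["time_s"].to_numpy()))
        if dt <= 0:
            raise StructuralError("cannot infer sampling rate: bad time_s column")
        sampling_rate = 1.0 / dt
    return COPTrajectory(
        ap=df["cop_ap_mm"].to_numpy(), ml=df["cop_ml_mm"].to_numpy(),
        sampling_rate=float(sampling_rate),
    )


def write_cop_csv(traj: COPTrajectory, path: str | Path) -> None:
    """Write a trajectory as time_s,cop_ap_mm,cop_ml_mm."""
    t = np.arange(traj.n_samples) / traj.sampling_rate
    df = pd.DataFrame(
        {"time_s": t, "cop_ap_mm": traj.ap, "cop_ml_mm": traj.ml}
    )
    df.to_csv(path, index=False, float_format="%.9g")
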