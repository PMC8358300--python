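"""Stabilometric measures of the center-of-pressure path.

Seven per-trial summary measures of quiet-standing sway, in the classic
time-domain battery:

* mean distance from the mean COP, per direction (``mean_ap``, ``mean_ml``,
  mm) — (1/N) Σ|x_i| on the centered series;
* mean velocity, per direction (``vel_ap``, ``vel_ml``, mm/s) — total
  excursion Σ|x_{i+1} − x_i| over the elapsed duration (N−1)/fs;
* 95% confidence-ellipse sway area (``area95``, mm²) — the covariance-based
  prediction ellipse expected to enclose ~95% of COP points,
  2π·F·sqrt(s_AP²·s_ML² − s_APML²) with F the 0.95 quantile of
  F(2, N−2) (→ 3.00 for large N);
* directional mean frequency (``mf_ap``, ``mf_ml``, Hz) — the frequency of
  the sinusoid whose path length matches the observed excursion relative to
  the mean distance, Mf = Vel / (4·√2·Mean).

All distance-like measures require an explicitly centered trajectory;
centering is never applied silently.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cop import COPTrajectory
from .errors import MeasureError

Axis = Literal["ap", "ml"]

#: quantile of the confidence ellipse (fraction of points it aims to cover)
DEFAULT_ELLIPSE_QUANTILE = 0.95

#: constant in the directional mean-frequency formula Mf = Vel / (C · Mean)
MF_CONSTANT = 4.0 * math.sqrt(2.0)

MEASURE_NAMES = ("mean_ap", "mean_ml", "vel_ap", "vel_ml",
                 "area95", "mf_ap", "mf_ml")


def _axis_series(traj: COPTrajectory, axis: Axis) -> np.ndarray:
    if axis not in ("ap", "ml"):
        raise MeasureError(f"axis must be 'ap' or 'ml', got {axis!r}")
    return traj.ap if axis == "ap" else traj.ml


def _require_centered(traj: COPTrajectory, op: str) -> None:
    if not traj.centered:
        raise MeasureError(
            f"{op} requires an explicitly centered trajectory; call "
            "center_trajectory or preprocess first"
        )


def mean_distance(traj: COPTrajectory, axis: Axis) -> float:
    """Average absolute distance (mm) from the mean COP along one axis."""
    _require_centered(traj, "mean_distance")
    if traj.n_samples < 2:
        raise MeasureError("mean_distance needs at least 2 samples")
    return float(np.mean(np.abs(_axis_series(traj, axis))))


def mean_velocity(traj: COPTrajectory, axis: Axis) -> float:
    """Average speed (mm/s) of the COP along one axis.

    Total excursion divided by the elapsed duration (N−1)/fs; centering does
    not affect it but is still required for battery consistency.
    """
    if traj.n_samples < 2:
        raise MeasureError("mean_velocity needs at least 2 samples")
    x = _axis_series(traj, axis)
    excursion = float(np.sum(np.abs(np.diff(x))))
    return excursion * traj.sampling_rate / (traj.n_samples - 1)


@dataclass(frozen=True)
class EllipseFit:
    """95% confidence ellipse of the COP scatter."""

    area: float          # mm²
    semi_axes: tuple[float, float]  # mm, major then minor
    angle: float         # rad, major axis vs the ML (x) axis
    f_critical: float    # quantile of F(2, N−2) used
    degenerate: bool


def ellipse_fit(
    traj: COPTrajectory, quantile: float = DEFAULT_ELLIPSE_QUANTILE
) -> EllipseFit:
    """Fit the covariance-based prediction ellipse to a centered path.

    The ellipse is {x : xᵀ S⁻¹ x ≤ 2F} with S the sample covariance of
    (AP, ML) and F the ``quantile`` point of F(2, N−2); its area is
    2π·F·sqrt(det S).  A collinear path (singular covariance) is flagged
    degenerate with area 0.
    """
    _require_centered(traj, "ellipse_fit")
    n = traj.n_samples
    if n < 3:
        raise MeasureError("ellipse_fit needs at least 3 samples")
    if not 0 < quantile < 1:
        raise MeasureError("ellipse quantile must be in (0, 1)")
    fcrit = float(stats.f.ppf(quantile, 2, n - 2))
    cov = np.cov(np.vstack([traj.ap, traj.ml]), ddof=1)
    det = float(np.linalg.det(cov))
    eigvals, eigvecs = np.linalg.eigh(cov)
    tol = 1e-12 * max(1.0, float(eigvals[-1]))
    if det <= tol or eigvals[0] <= tol:
        return EllipseFit(area=0.0, semi_axes=(0.0, 0.0), angle=0.0,
                          f_critical=fcrit, degenerate=True)
    area = 2.0 * math.pi * fcrit * math.sqrt(det)
    semi = tuple(sorted((math.sqrt(2.0 * fcrit * v) for v in eigvals),
                        reverse=True))
    major = eigvecs[:, int(np.argmax(eigvals))]
    angle = math.atan2(major[1], major[0])  # component order: (ap, ml)
    return EllipseFit(area=area, semi_axes=semi, angle=angle,
                      f_critical=fcrit, degenerate=False)


def ellipse_area_95(
    traj: COPTrajectory, quantile: float = DEFAULT_ELLIPSE_QUANTILE
) -> float:
    """Area (mm²) of the 95% confidence ellipse; 0 for a degenerate path."""
    return ellipse_fit(traj, quantile).area


def ellipse_coverage(
    traj: COPTrajectory, quantile: float = DEFAULT_ELLIPSE_QUANTILE
) -> float:
    """Fraction of the path's points inside its own fitted ellipse."""
    fit = ellipse_fit(traj, quantile)
    if fit.degenerate:
        return float("nan")
    cov = np.cov(np.vstack([traj.ap, traj.ml]), ddof=1)
    inv = np.linalg.inv(cov)
    pts = np.vstack([traj.ap, traj.ml])
    d2 = np.einsum("ij,ji->i", pts.T @ inv, pts)
    return float(np.mean(d2 <= 2.0 * fit.f_critical))


def mean_frequency(
    traj: COPTrajectory, axis: Axis, constant: float = MF_CONSTANT
) -> float:
    """Directional mean frequency (Hz): Vel / (4·√2·Mean).

    Equivalently, the frequency of a sinusoid whose total path length per
    unit mean distance matches the observed path.  Returns NaN (flagged
    undefined upstream) when the mean distance is zero.
    """
    m = mean_distance(traj, axis)
    if m == 0.0:
        return float("nan")
    return mean_velocity(traj, axis) / (constant * m)


@dataclass(frozen=True)
class MeasureBattery:
    """The seven sway measures for one trial or a trial aggregate.

    Measures that are undefined on the input (e.g. mean frequency of a
    constant series) are NaN and listed in ``undefined``; they are never
    silently dropped.
    """

    mean_ap: float
    mean_ml: float
    vel_ap: float
    vel_ml: float
    area95: float
    mf_ap: float
    mf_ml: float
    n_samples: int
    duration: float
    undefined: frozenset[str] = frozenset()
    label: tuple | None = None

    def value(self, name: str) -> float:
        if name not in MEASURE_NAMES:
            raise MeasureError(f"unknown measure {name!r}")
        return getattr(self, name)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in MEASURE_NAMES}


def measure_battery(
    traj: COPTrajectory,
    ellipse_quantile: float = DEFAULT_ELLIPSE_QUANTILE,
    mf_constant: float = MF_CONSTANT,
) -> MeasureBattery:
    """Compute all seven measures on a preprocessed (centered) trial."""
    _require_centered(traj, "measure_battery")
    try:
        vals = {
            "mean_ap": mean_distance(traj, "ap"),
            "mean_ml": mean_distance(traj, "ml"),
            "vel_ap": mean_velocity(traj, "ap"),
            "vel_ml": mean_velocity(traj, "ml"),
            "area95": ellipse_area_95(traj, ellipse_quantile),
            "mf_ap": mean_frequency(traj, "ap", mf_constant),
            "mf_ml": mean_frequency(traj, "ml", mf_constant),
        }
    except MeasureError as err:
        raise MeasureError(f"trial {traj.label}: {err}") from err
    undefined = frozenset(k for k, v in vals.items() if math.isnan(v))
    return MeasureBattery(
        **vals, n_samples=traj.n_samples, duration=traj.duration,
        undefined=undefined, label=traj.label,
    )


def aggregate(
    trials: Sequence[MeasureBattery], method: str = "mean"
) -> MeasureBattery:
    """Reduce several trials of one participant-condition to one battery.

    Per-field arithmetic mean (or median); a measure undefined in any trial
    is undefined in the aggregate.
    """
    if not trials:
        raise MeasureError("aggregate needs at least one trial")
    if method not in ("mean", "median"):
        raise MeasureError(f"unknown aggregation method {method!r}")
    reducer = np.mean if method == "mean" else np.median
    undefined = frozenset().union(*(t.undefined for t in trials))
    vals = {}
    for name in MEASURE_NAMES:
        if name in undefined:
            vals[name] = float("nan")
        else:
            vals[name] = float(reducer([t.value(name) for t in trials]))
    return MeasureBattery(
        **vals,
        n_samples=int(np.sum([t.n_samples for t in trials])),
        duration=float(np.sum([t.duration for t in trials])),
        undefined=undefined,
        label=trials[0].label,
    )


# ---------------------------------------------------------------------------
# Long-format hand-off to the condition statistics

LONG_COLUMNS = ["participant", "condition", "trial", "measure", "value", "flag"]


def batteries_to_long(
    records: Iterable[tuple[object, int, object, MeasureBattery]]
) -> pd.DataFrame:
    """Flatten (participant, condition, trial, battery) records to long form.

    ``trial`` may be an int or e.g. "agg" for a trial aggregate.  ``flag``
    is "undefined" for NaN measures, empty otherwise.
    """
    rows = []
    for participant, condition, trial, bat in records:
        for name in MEASURE_NAMES:
            rows.append({
                "participant": participant,
                "condition": int(condition),
                "trial": trial,
                "measure": name,
                "value": bat.value(name),
                "flag": "undefined" if name in bat.undefined else "",
            })
    return pd.DataFrame(rows, columns=LONG_COLUMNS)


def write_long_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def read_long_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python",
                     keep_default_na=True)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise MeasureError(f"measures CSV {path} missing columns {missing}")
    df["flag"] = df["flag"].fillna("")
    return df
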