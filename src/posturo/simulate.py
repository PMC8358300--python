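"""Seeded synthetic sway cohorts and the VR surround motion profile.

The sway model is deliberately simple: each axis of each trial is
zero-phase low-pass-filtered Gaussian white noise, rescaled to a target
RMS amplitude.  Amplitude and bandwidth steer the distance-type and
frequency-type stabilometric measures nearly independently, which is all
the downstream analysis assumes; it is a statistical stand-in, not a
biomechanical model of posture.

A cohort draws one multiplicative amplitude effect per participant
(log-normal, scale τ) shared across all of that participant's conditions —
this induces the within-subject correlation that repeated-measures
statistics exploit — plus independent log-normal trial-to-trial noise.

``calibrate_defaults`` tunes per-condition RMS and cutoff so the cohort's
mean directional distances and mean frequencies match published
cohort-level values for healthy young adults across the six
sensory-organization conditions; the fitted parameters ship as a versioned
YAML data asset and are what :func:`default_params` returns.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from typing import Mapping

import numpy as np
import yaml
from scipy import signal

from .cop import COPTrajectory, center_trajectory
from .errors import ConfigError
from .measures import MeasureBattery, aggregate, batteries_to_long, measure_battery

#: published per-condition cohort means (healthy young adults, n=23) used
#: as calibration targets: mean distance (mm) and mean frequency (Hz).
REFERENCE_CONDITION_MEANS: dict[int, dict[str, float]] = {
    1: {"mean_ap": 3.71, "mean_ml": 1.33, "mf_ap": 0.92, "mf_ml": 1.49},
    2: {"mean_ap": 4.17, "mean_ml": 1.61, "mf_ap": 0.96, "mf_ml": 1.39},
    3: {"mean_ap": 3.90, "mean_ml": 1.73, "mf_ap": 0.96, "mf_ml": 1.38},
    4: {"mean_ap": 5.50, "mean_ml": 3.15, "mf_ap": 1.03, "mf_ml": 0.96},
    5: {"mean_ap": 5.92, "mean_ml": 3.24, "mf_ap": 1.06, "mf_ml": 0.96},
    6: {"mean_ap": 5.92, "mean_ml": 3.12, "mf_ap": 0.98, "mf_ml": 0.91},
}

FOAM_CONDITIONS = (4, 5, 6)


@dataclass(frozen=True)
class SurroundMotionProfile:
    """Sinusoidal anteroposterior tilt of the VR surround panels.

    The panels swing to a maximum angle A with a maximum angular velocity
    Vmax, which for a sinusoid θ(t) = A·sin(2π f t) fixes the frequency at
    f = Vmax / (2πA) ≈ 0.1194 Hz at the defaults (A=20°, Vmax=15°/s).
    """

    amplitude_deg: float = 20.0
    peak_velocity_deg_s: float = 15.0
    duration_s: float = 60.0
    sampling_rate: float = 200.0

    def __post_init__(self):
        if self.amplitude_deg <= 0:
            raise ConfigError("surround amplitude must be positive")
        if self.peak_velocity_deg_s <= 0:
            raise ConfigError("surround peak velocity must be positive")
        if self.duration_s <= 0 or self.sampling_rate <= 0:
            raise ConfigError("duration and sampling rate must be positive")

    @property
    def frequency_hz(self) -> float:
        return self.peak_velocity_deg_s / (2.0 * math.pi * self.amplitude_deg)


def surround_motion(
    profile: SurroundMotionProfile | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled panel angle series: (time_s, theta_deg)."""
    if profile is None:
        profile = SurroundMotionProfile()
    n = round(profile.duration_s * profile.sampling_rate) + 1
    t = np.arange(n) / profile.sampling_rate
    theta = profile.amplitude_deg * np.sin(
        2.0 * math.pi * profile.frequency_hz * t
    )
    return t, theta


@dataclass(frozen=True)
class ConditionSway:
    """Generator parameters for one condition: RMS amplitude (mm) and
    low-pass bandwidth (Hz) per axis."""

    rms_ap_mm: float
    rms_ml_mm: float
    cutoff_ap_hz: float
    cutoff_ml_hz: float


@dataclass(frozen=True)
class SwayParams:
    """Full generator configuration.

    ``tau`` is the SD of the log-normal participant amplitude effect
    (log-mm scale); ``trial_noise`` the SD of the log-normal trial-level
    amplitude jitter (as a log fraction).
    """

    conditions: Mapping[int, ConditionSway]
    tau: float = 0.25
    trial_noise: float = 0.10
    sampling_rate: float = 200.0
    trial_duration: float = 20.0
    filter_order: int = 4

    def __post_init__(self):
        if not self.conditions:
            raise ConfigError("SwayParams needs at least one condition")
        nyq = self.sampling_rate / 2.0
        for c, cs in self.conditions.items():
            for name in ("rms_ap_mm", "rms_ml_mm"):
                if getattr(cs, name) <= 0:
                    raise ConfigError(f"condition {c}: {name} must be positive")
            for name in ("cutoff_ap_hz", "cutoff_ml_hz"):
                v = getattr(cs, name)
                if not 0 < v < nyq:
                    raise ConfigError(
                        f"condition {c}: {name}={v:g} Hz outside (0, "
                        f"Nyquist={nyq:g})"
                    )
        if self.tau < 0 or self.trial_noise < 0:
            raise ConfigError("tau and trial_noise must be non-negative")
        # foam conditions (4-6), when present, must not be gentler than the
        # firm baseline
        if 1 in self.conditions:
            base = self.conditions[1]
            for c in FOAM_CONDITIONS:
                if c in self.conditions:
                    cs = self.conditions[c]
                    if (cs.rms_ap_mm < base.rms_ap_mm
                            or cs.rms_ml_mm < base.rms_ml_mm):
                        raise ConfigError(
                            f"foam condition {c} amplitude below the firm "
                            "baseline (condition 1)"
                        )

    @property
    def n_samples(self) -> int:
        return round(self.trial_duration * self.sampling_rate)


@dataclass
class SwayCohort:
    """Generated trials keyed (participant, condition, trial), 1-based."""

    trials: dict[tuple[int, int, int], COPTrajectory]
    params: SwayParams
    participant_effects: dict[int, float]
    seed: int

    @property
    def n_participants(self) -> int:
        return len(self.participant_effects)

    def participants(self) -> list[int]:
        return sorted(self.participant_effects)


@lru_cache(maxsize=128)
def _butter_sos(order: int, cutoff: float, fs: float):
    return signal.butter(order, cutoff, btype="low", fs=fs, output="sos")


def _filtered_noise(rng: np.random.Generator, n: int, cutoff: float,
                    fs: float, order: int) -> np.ndarray:
    white = rng.standard_normal(n)
    x = signal.sosfiltfilt(_butter_sos(order, cutoff, fs), white)
    x = x - x.mean()
    sd = x.std()
    if sd == 0:  # pathological; keep a flat series rather than divide by 0
        return x
    return x / sd


def generate_trial(
    params: SwayParams,
    condition: int,
    participant_effect: float = 1.0,
    seed: int | np.random.Generator | None = 0,
) -> COPTrajectory:
    """One trial of synthetic sway for one condition.

    AP and ML are independent filtered-noise series rescaled to the
    condition's target RMS × participant effect × log-normal trial jitter.
    Bit-identical under identical (params, effect, seed).
    """
    if condition not in params.conditions:
        raise ConfigError(f"condition {condition} not in params")
    if participant_effect <= 0:
        raise ConfigError("participant_effect must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    cs = params.conditions[condition]
    n = params.n_samples
    out = {}
    for axis, rms, cutoff in (
        ("ap", cs.rms_ap_mm, cs.cutoff_ap_hz),
        ("ml", cs.rms_ml_mm, cs.cutoff_ml_hz),
    ):
        jitter = math.exp(rng.normal(0.0, params.trial_noise))
        x = _filtered_noise(rng, n, cutoff, params.sampling_rate,
                            params.filter_order)
        out[axis] = x * rms * participant_effect * jitter
    return COPTrajectory(ap=out["ap"], ml=out["ml"],
                         sampling_rate=params.sampling_rate, centered=False)


def generate_cohort(
    params: SwayParams | None = None,
    n_participants: int = 23,
    trials_per_condition: int = 3,
    seed: int = 0,
) -> SwayCohort:
    """Full factorial cohort: every participant × condition × trial.

    Participant amplitude effects exp(N(0, τ²)) are drawn once per
    participant and shared across conditions, inducing the within-subject
    correlation that the repeated-measures contrasts rely on.
    """
    if params is None:
        params = default_params()
    if n_participants < 1 or trials_per_condition < 1:
        raise ConfigError("cohort needs >= 1 participant and trial")
    root = np.random.SeedSequence(seed)
    effect_rng = np.random.default_rng(root.spawn(1)[0])
    effects = {
        p + 1: float(math.exp(effect_rng.normal(0.0, params.tau)))
        for p in range(n_participants)
    }
    trials: dict[tuple[int, int, int], COPTrajectory] = {}
    conditions = sorted(params.conditions)
    streams = root.spawn(n_participants * len(conditions) * trials_per_condition)
    i = 0
    for p in range(1, n_participants + 1):
        for c in conditions:
            for t in range(1, trials_per_condition + 1):
                rng = np.random.default_rng(streams[i])
                i += 1
                traj = generate_trial(params, c, effects[p], rng)
                traj.label = (c, t)
                trials[(p, c, t)] = traj
    return SwayCohort(trials=trials, params=params,
                      participant_effects=effects, seed=seed)


def cohort_measures(cohort: SwayCohort, aggregate_trials: bool = True):
    """Run the stabilometry battery over a cohort.

    Returns a long-format DataFrame (participant, condition, trial, measure,
    value, flag); with ``aggregate_trials`` the trials of each
    participant-condition are averaged first (trial column = 'agg').
    """
    per_pc: dict[tuple[int, int], list[MeasureBattery]] = {}
    records = []
    for (p, c, t), traj in sorted(cohort.trials.items()):
        bat = measure_battery(center_trajectory(traj))
        if aggregate_trials:
            per_pc.setdefault((p, c), []).append(bat)
        else:
            records.append((p, c, t, bat))
    if aggregate_trials:
        for (p, c), bats in sorted(per_pc.items()):
            records.append((p, c, "agg", aggregate(bats)))
    return batteries_to_long(records)


# ---------------------------------------------------------------------------
# Calibration

#: E|X| / sd for a centered Gaussian: sqrt(2/pi)
_GAUSS_ABS_MEAN = math.sqrt(2.0 / math.pi)


@dataclass
class CalibrationResult:
    params: SwayParams
    converged: bool
    n_iterations: int
    residuals: dict[int, dict[str, float]] = field(default_factory=dict)

    def report(self) -> str:
        lines = [
            f"calibration {'converged' if self.converged else 'DID NOT converge'}"
            f" after {self.n_iterations} iterations; worst relative residuals:"
        ]
        for c, res in sorted(self.residuals.items()):
            worst = max(res, key=lambda k: abs(res[k]))
            lines.append(f"  condition {c}: {worst} {res[worst]:+.3f}")
        return "\n".join(lines)


def calibrate_defaults(
    targets: Mapping[int, Mapping[str, float]] = REFERENCE_CONDITION_MEANS,
    tolerance: float = 0.05,
    n_participants: int = 23,
    trials_per_condition: int = 3,
    seed: int = 2021,
    max_iterations: int = 15,
    tau: float = 0.25,
    trial_noise: float = 0.10,
) -> CalibrationResult:
    """Fit per-condition RMS and cutoff to target measure means.

    Iterates simulate → compare cohort means of mean_ap/mean_ml and
    mf_ap/mf_ml to targets → multiplicative update (RMS tracks mean
    distance, cutoff tracks mean frequency, which are nearly decoupled in
    the filtered-noise model), until every relative error is within
    ``tolerance`` or the iteration budget runs out.
    """
    for c, tgt in targets.items():
        for key in ("mean_ap", "mean_ml", "mf_ap", "mf_ml"):
            if key not in tgt:
                raise ConfigError(f"condition {c}: target missing {key!r}")
            if tgt[key] <= 0:
                raise ConfigError(
                    f"condition {c}: degenerate target {key}={tgt[key]!r}"
                )
    # closed-form initialization: mean distance = sigma*sqrt(2/pi); mean
    # frequency scales ~linearly with the cutoff (~0.64*fc for an ideal
    # brick-wall filter; the iteration absorbs the Butterworth difference)
    conditions = {}
    for c, tgt in targets.items():
        conditions[c] = ConditionSway(
            rms_ap_mm=tgt["mean_ap"] / _GAUSS_ABS_MEAN,
            rms_ml_mm=tgt["mean_ml"] / _GAUSS_ABS_MEAN,
            cutoff_ap_hz=max(0.05, tgt["mf_ap"] / 0.64),
            cutoff_ml_hz=max(0.05, tgt["mf_ml"] / 0.64),
        )
    params = SwayParams(conditions=conditions, tau=tau, trial_noise=trial_noise)

    residuals: dict[int, dict[str, float]] = {}
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        cohort = generate_cohort(params, n_participants=n_participants,
                                 trials_per_condition=trials_per_condition,
                                 seed=seed)
        long_df = cohort_measures(cohort, aggregate_trials=True)
        sim = (long_df.pivot_table(index="condition", columns="measure",
                                   values="value", aggfunc="mean"))
        new_conditions = {}
        worst = 0.0
        residuals = {}
        for c, tgt in targets.items():
            cs = params.conditions[c]
            res = {}
            for key in ("mean_ap", "mean_ml", "mf_ap", "mf_ml"):
                res[key] = float(sim.at[c, key] / tgt[key] - 1.0)
                worst = max(worst, abs(res[key]))
            residuals[c] = res
            new_conditions[c] = ConditionSway(
                rms_ap_mm=cs.rms_ap_mm / (1.0 + res["mean_ap"]),
                rms_ml_mm=cs.rms_ml_mm / (1.0 + res["mean_ml"]),
                cutoff_ap_hz=cs.cutoff_ap_hz / (1.0 + res["mf_ap"]),
                cutoff_ml_hz=cs.cutoff_ml_hz / (1.0 + res["mf_ml"]),
            )
        if worst <= tolerance:
            converged = True
            break
        params = replace(params, conditions=new_conditions)
    return CalibrationResult(params=params, converged=converged,
                             n_iterations=it, residuals=residuals)


def params_to_yaml(params: SwayParams) -> str:
    doc = {
        "tau": params.tau,
        "trial_noise": params.trial_noise,
        "sampling_rate": params.sampling_rate,
        "trial_duration": params.trial_duration,
        "filter_order": params.filter_order,
        "conditions": {
            int(c): {
                "rms_ap_mm": round(cs.rms_ap_mm, 6),
                "rms_ml_mm": round(cs.rms_ml_mm, 6),
                "cutoff_ap_hz": round(cs.cutoff_ap_hz, 6),
                "cutoff_ml_hz": round(cs.cutoff_ml_hz, 6),
            }
            for c, cs in params.conditions.items()
        },
    }
    return yaml.safe_dump(doc, sort_keys=True)


def params_from_yaml(text: str) -> SwayParams:
    doc = yaml.safe_load(text)
    conditions = {
        int(c): ConditionSway(**cs) for c, cs in doc["conditions"].items()
    }
    return SwayParams(
        conditions=conditions, tau=doc["tau"], trial_noise=doc["trial_noise"],
        sampling_rate=doc["sampling_rate"],
        trial_duration=doc["trial_duration"],
        filter_order=doc["filter_order"],
    )


def trajectory_to_forces(traj: COPTrajectory, body_weight_n: float = 700.0):
    """Back-compute a plausible force-plate recording from a COP path.

    Constant vertical load (default ~70 kg body weight), zero shear and
    free moment; plate moments follow from the COP under the default axis
    convention (AP ≡ plate x, ML ≡ plate y, sensor origin at the surface).
    Lets synthetic cohorts exercise the full force-ingestion path.
    """
    from .cop import ForcePlateRecording  # local import avoids cycle noise

    if body_weight_n <= 0:
        raise ConfigError("body_weight_n must be positive")
    n = traj.n_samples
    t = np.arange(n) / traj.sampling_rate
    fz = np.full(n, body_weight_n)
    ap_m = traj.ap / 1000.0
    ml_m = traj.ml / 1000.0
    return ForcePlateRecording(
        time=t,
        fx=np.zeros(n), fy=np.zeros(n), fz=fz,
        mx=ml_m * fz, my=-ap_m * fz, mz=np.zeros(n),
        sampling_rate=traj.sampling_rate,
    )


def default_params() -> SwayParams:
    """The calibrated six-condition defaults shipped with the package."""
    text = resources.files("posturo.data").joinpath(
        "sway_defaults.yaml").read_text()
    return params_from_yaml(text)
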