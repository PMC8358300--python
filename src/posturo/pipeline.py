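"""End-to-end orchestration: simulate, analyze, score.

Thin deterministic glue over the library modules: a validated run
configuration, cohort file layouts, and report rendering.  Every artifact
is reproducible byte-for-byte from (config, inputs, seed): CSV numeric
formatting is pinned and JSON is emitted with sorted keys.
"""
from __future__ import annotations

import hashlib
import json
import math
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cop import (
    AxisMap,
    FilterSpec,
    compute_cop,
    preprocess,
    read_cop_csv,
    read_force_csv,
    write_cop_csv,
)
from .errors import ConfigError, StructuralError, ValidationError
from .measures import (
    MEASURE_NAMES,
    aggregate,
    batteries_to_long,
    measure_battery,
    read_long_csv,
    write_long_csv,
)
from .questionnaires import classify_ssq, score_ipq, score_ssq, score_sus
from .simulate import SwayParams, default_params, generate_cohort, params_to_yaml
from .stats import (
    DEFAULT_CONTRASTS,
    contrasts_to_frame,
    omnibus_to_frame,
    run_contrasts,
)

TRIAL_FILE_RE = re.compile(r"p(\d+)_c(\d+)_t(\d+)\.csv$")

#: significance markers per contrast in the report's condition table
CONTRAST_MARKERS = {(2, 1): "a", (4, 1): "b", (5, 1): "c", (6, 5): "d"}


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    seed: int = 0
    log_level: str = "INFO"
    sampling_rate: float = 200.0
    plate_origin_offset_h: float = 0.0
    axis_map: AxisMap = field(default_factory=AxisMap)
    filter: FilterSpec | None = None
    ellipse_quantile: float = 0.95
    mf_constant: float = 4.0 * math.sqrt(2.0)
    alpha: float = 0.05
    contrasts: tuple[tuple[int, int], ...] = DEFAULT_CONTRASTS
    n_participants: int = 23
    trials_per_condition: int = 3
    sway_params: SwayParams | None = None  # None -> calibrated defaults

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if not self.contrasts:
            raise ConfigError("contrast list must be non-empty")
        if not 0 < self.ellipse_quantile < 1:
            raise ConfigError("ellipse_quantile must be in (0, 1)")
        if self.mf_constant <= 0:
            raise ConfigError("mf_constant must be positive")
        if self.n_participants < 1 or self.trials_per_condition < 1:
            raise ConfigError("cohort sizes must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        kw: dict = {}
        for key in ("seed", "log_level"):
            if key in doc:
                kw[key] = doc[key]
        acq = doc.get("acquisition", {})
        if "sampling_rate" in acq:
            kw["sampling_rate"] = float(acq["sampling_rate"])
        if "h" in acq:
            kw["plate_origin_offset_h"] = float(acq["h"])
        if "axis_map" in acq:
            kw["axis_map"] = AxisMap(**acq["axis_map"])
        if acq.get("filter"):
            kw["filter"] = FilterSpec(**acq["filter"])
        meas = doc.get("measures", {})
        if "ellipse_quantile" in meas:
            kw["ellipse_quantile"] = float(meas["ellipse_quantile"])
        if "mf_constant" in meas:
            kw["mf_constant"] = float(meas["mf_constant"])
        st = doc.get("stats", {})
        if "alpha" in st:
            kw["alpha"] = float(st["alpha"])
        if "contrasts" in st:
            kw["contrasts"] = tuple(tuple(int(x) for x in c)
                                    for c in st["contrasts"])
        syn = doc.get("synthetic", {})
        if "n_participants" in syn:
            kw["n_participants"] = int(syn["n_participants"])
        if "trials_per_condition" in syn:
            kw["trials_per_condition"] = int(syn["trials_per_condition"])
        return cls(**kw)

    def digest(self) -> str:
        doc = {
            "seed": self.seed,
            "sampling_rate": self.sampling_rate,
            "h": self.plate_origin_offset_h,
            "axis_map": asdict(self.axis_map),
            "filter": asdict(self.filter) if self.filter else None,
            "ellipse_quantile": self.ellipse_quantile,
            "mf_constant": self.mf_constant,
            "alpha": self.alpha,
            "contrasts": [list(c) for c in self.contrasts],
            "n_participants": self.n_participants,
            "trials_per_condition": self.trials_per_condition,
        }
        blob = json.dumps(doc, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# simulate


def cmd_simulate(config: RunConfig, out_dir: str | Path) -> list[Path]:
    """Write a seeded synthetic cohort as per-trial COP CSVs.

    Layout: ``<out>/p{participant:02d}_c{condition}_t{trial}.csv`` plus a
    ground-truth ``sway_params.yaml`` sidecar and a ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.sway_params or default_params()
    cohort = generate_cohort(params, n_participants=config.n_participants,
                             trials_per_condition=config.trials_per_condition,
                             seed=config.seed)
    written = []
    for (p, c, t), traj in sorted(cohort.trials.items()):
        path = out / f"p{p:02d}_c{c}_t{t}.csv"
        write_cop_csv(traj, path)
        written.append(path)
    (out / "sway_params.yaml").write_text(params_to_yaml(params))
    manifest = {
        "seed": config.seed,
        "n_participants": config.n_participants,
        "trials_per_condition": config.trials_per_condition,
        "n_trials": len(written),
        "config_digest": config.digest(),
        "version": __version__,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n"
    )
    return written


# ---------------------------------------------------------------------------
# analyze


def _read_trial(path: Path, config: RunConfig):
    header = pd.read_csv(path, sep=None, engine="python", nrows=0)
    if "fz" in header.columns:
        rec = read_force_csv(
            path, plate_origin_offset_h=config.plate_origin_offset_h,
            axis_map=config.axis_map,
        )
        return compute_cop(rec)
    return read_cop_csv(path)


def compute_measures_from_dir(input_dir: str | Path,
                              config: RunConfig) -> pd.DataFrame:
    """Measure batteries for every trial file in a cohort directory.

    Files must match ``p*_c*_t*.csv`` and may hold either COP columns
    (time_s,cop_ap_mm,cop_ml_mm) or raw force-plate columns
    (time,fx..mz); force files go through COP derivation first.  Trials
    are preprocessed (optional filter + centering) and aggregated per
    participant-condition.
    """
    input_dir = Path(input_dir)
    files = sorted(input_dir.glob("*.csv"))
    entries = []
    for path in files:
        m = TRIAL_FILE_RE.search(path.name)
        if m:
            entries.append((int(m.group(1)), int(m.group(2)),
                            int(m.group(3)), path))
    if not entries:
        raise StructuralError(
            f"no trial files matching 'p*_c*_t*.csv' in {input_dir}"
        )
    per_pc: dict[tuple[int, int], list] = {}
    for p, c, t, path in entries:
        traj = _read_trial(path, config)
        traj = preprocess(traj, config.filter)
        bat = measure_battery(traj, ellipse_quantile=config.ellipse_quantile,
                              mf_constant=config.mf_constant)
        per_pc.setdefault((p, c), []).append(bat)
    records = [(p, c, "agg", aggregate(bats))
               for (p, c), bats in sorted(per_pc.items())]
    return batteries_to_long(records)


def _fmt(x: float) -> str:
    return "nan" if not np.isfinite(x) else f"{x:.2f}"


def build_report(long_df: pd.DataFrame, config: RunConfig) -> dict:
    """Assemble the study report: per-condition table, omnibus, contrasts.

    Returns a JSON-serializable dict; :func:`render_report_markdown` turns
    it into the human-readable table.
    """
    reports = run_contrasts(long_df, contrasts=config.contrasts,
                            alpha=config.alpha)
    conditions = sorted(long_df["condition"].unique().tolist())
    table: dict[str, dict] = {}
    for rep in reports:
        sub = long_df[(long_df["measure"] == rep.measure)
                      & (long_df["flag"] == "")]
        row = {}
        for c in conditions:
            vals = sub[sub["condition"] == c]["value"]
            n_flagged = int((long_df[(long_df["measure"] == rep.measure)
                                     & (long_df["condition"] == c)]["flag"]
                             != "").sum())
            markers = "".join(
                CONTRAST_MARKERS.get(res.contrast, "*")
                for res in rep.contrasts
                if res.contrast[0] == c and not res.degenerate
                and res.p_value < config.alpha
            )
            row[str(c)] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "n": int(len(vals)),
                "n_flagged": n_flagged,
                "markers": markers,
            }
        table[rep.measure] = row
    return {
        "condition_table": table,
        "omnibus": omnibus_to_frame(reports).to_dict(orient="records"),
        "contrasts": contrasts_to_frame(reports).to_dict(orient="records"),
        "provenance": {
            "config_digest": config.digest(),
            "seed": config.seed,
            "alpha": config.alpha,
            "version": __version__,
            "multiplicity_adjustment": "none (a-priori contrasts; "
                                       "interpret marker inflation accordingly)",
        },
    }


def render_report_markdown(report: dict, config: RunConfig) -> str:
    conditions = sorted(
        {c for row in report["condition_table"].values() for c in row},
        key=int,
    )
    lines = ["# Condition comparison report", ""]
    lines.append("Per-condition values are mean (SD) across participants "
                 "after trial aggregation.")
    lines.append("")
    lines.append("| Measure | " + " | ".join(f"Condition {c}"
                                             for c in conditions) + " |")
    lines.append("|" + "---|" * (len(conditions) + 1))
    for measure in MEASURE_NAMES:
        if measure not in report["condition_table"]:
            continue
        cells = []
        for c in conditions:
            cell = report["condition_table"][measure][c]
            text = f"{_fmt(cell['mean'])} ({_fmt(cell['sd'])})"
            if cell["markers"]:
                text += " " + cell["markers"]
            if cell["n_flagged"]:
                text += f" [excl {cell['n_flagged']}]"
            cells.append(text)
        lines.append(f"| {measure} | " + " | ".join(cells) + " |")
    lines.append("")
    marks = ", ".join(
        f"{sym}: {a} vs {b} p < {config.alpha:g}"
        for (a, b), sym in CONTRAST_MARKERS.items()
        if (a, b) in config.contrasts
    )
    lines.append(f"Markers — {marks}. No multiplicity adjustment "
                 "(a-priori contrasts).")
    lines.append("")
    lines.append("## Friedman omnibus")
    lines.append("")
    lines.append("| Measure | chi2_F | df | p | n |")
    lines.append("|---|---|---|---|---|")
    for rec in report["omnibus"]:
        lines.append(
            f"| {rec['measure']} | {rec['chi2_f']:.2f} | {rec['df']} | "
            f"{rec['p_value']:.3g} | {rec['n']} |"
        )
    lines.append("")
    prov = report["provenance"]
    lines.append(f"Provenance: config {prov['config_digest']}, seed "
                 f"{prov['seed']}, posturo {prov['version']}.")
    return "\n".join(lines) + "\n"


def cmd_analyze(input_path: str | Path, config: RunConfig,
                out_dir: str | Path) -> dict:
    """Ingest a cohort, compute measures and statistics, write artifacts.

    ``input_path`` is either a directory of per-trial CSVs (COP or force)
    or an already-computed long measures CSV.  Writes measures.csv,
    omnibus.csv, contrasts.csv, report.md and report.json under ``out_dir``
    and returns the report dict.
    """
    input_path = Path(input_path)
    if input_path.is_dir():
        long_df = compute_measures_from_dir(input_path, config)
    else:
        long_df = read_long_csv(input_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = build_report(long_df, config)
    write_long_csv(long_df, out / "measures.csv")
    contrasts_df = pd.DataFrame(report["contrasts"])
    omnibus_df = pd.DataFrame(report["omnibus"])
    contrasts_df.to_csv(out / "contrasts.csv", index=False,
                        float_format="%.12g")
    omnibus_df.to_csv(out / "omnibus.csv", index=False, float_format="%.12g")
    (out / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=2) + "\n"
    )
    (out / "report.md").write_text(render_report_markdown(report, config))
    return report


# ---------------------------------------------------------------------------
# score

def _score_ssq_row(m):
    s = score_ssq(m)
    return {"nausea": s.nausea, "oculomotor": s.oculomotor,
            "disorientation": s.disorientation, "total": s.total}


def _score_ipq_row(m):
    s = score_ipq(m)
    return {"total": s.total, "general": s.general, "spatial": s.spatial,
            "involvement": s.involvement, "realism": s.realism}


_SCORERS = {
    "ssq": _score_ssq_row,
    "ipq": _score_ipq_row,
    "sus": lambda m: {"total": score_sus(m)},
}


def cmd_score(responses_csv: str | Path, out_dir: str | Path) -> pd.DataFrame:
    """Batch-score a long responses CSV (participant,instrument,item,rating).

    Writes scores.csv (participant,instrument,scale,score) with appended
    summary mean/SD rows per scale, and an errors.csv sidecar listing rows
    that failed validation (those participants are skipped, not guessed).
    """
    df = pd.read_csv(responses_csv, sep=None, engine="python")
    for col in ("participant", "instrument", "item", "rating"):
        if col not in df.columns:
            raise StructuralError(
                f"responses CSV missing column {col!r}"
            )
    rows, errors = [], []
    for (participant, instrument), grp in df.groupby(
            ["participant", "instrument"], sort=True):
        name = str(instrument).lower()
        if name not in _SCORERS:
            errors.append({"participant": participant,
                           "instrument": instrument,
                           "error": f"unknown instrument {instrument!r}"})
            continue
        mapping = {int(r["item"]): r["rating"] for _, r in grp.iterrows()}
        try:
            scores = _SCORERS[name](mapping)
        except (ValidationError, ValueError) as err:
            errors.append({"participant": participant,
                           "instrument": instrument, "error": str(err)})
            continue
        for scale, score in scores.items():
            rows.append({"participant": participant, "instrument": name,
                         "scale": scale, "score": float(score)})
        if name == "ssq":
            rows.append({"participant": participant, "instrument": name,
                         "scale": "actively_ill",
                         "score": float(classify_ssq(scores["total"])
                                        == "actively_ill")})
    scores_df = pd.DataFrame(rows,
                             columns=["participant", "instrument", "scale",
                                      "score"])
    summary_rows = []
    for (instrument, scale), grp in scores_df.groupby(
            ["instrument", "scale"], sort=True):
        summary_rows.append({
            "participant": "summary_mean", "instrument": instrument,
            "scale": scale, "score": float(grp["score"].mean()),
        })
        summary_rows.append({
            "participant": "summary_sd", "instrument": instrument,
            "scale": scale,
            "score": float(grp["score"].std(ddof=1))
            if len(grp) > 1 else 0.0,
        })
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    full = pd.concat([scores_df, pd.DataFrame(summary_rows)],
                     ignore_index=True)
    full.to_csv(out / "scores.csv", index=False, float_format="%.12g")
    pd.DataFrame(errors, columns=["participant", "instrument", "error"]) \
        .to_csv(out / "errors.csv", index=False)
    return full
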