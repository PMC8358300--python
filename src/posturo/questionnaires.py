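"""Scoring of the three VR human-factors instruments.

* SSQ — Simulator Sickness Questionnaire: 16 symptoms rated 0–3, three
  overlapping 7-item subscales (nausea, oculomotor, disorientation) scored
  as raw-sum × weight (9.54 / 7.58 / 13.92); total = (sum of the three raw
  subscale sums) × 3.74.  A total above 100 classifies the respondent as
  actively ill from simulator sickness.
* iPQ — igroup Presence Questionnaire: 14 items rated 1–5 here; one
  general-presence item plus spatial presence (5), involvement (4) and
  experienced realism (4).  Scale maximum 70, neutral reference 35.
* SUS — System Usability Scale: 10 items rated 1–5, alternating keying,
  Brooke composite on 0–100.

Item→subscale maps ship as editable YAML data assets.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import yaml

from .errors import ValidationError

SSQ_ACTIVELY_ILL_THRESHOLD = 100.0


def _load_asset(name: str) -> dict:
    with resources.files("posturo.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


_SSQ = _load_asset("ssq_items.yaml")
_IPQ = _load_asset("ipq_items.yaml")

SSQ_SUBSCALES = ("nausea", "oculomotor", "disorientation")


@dataclass(frozen=True)
class SSQScores:
    nausea: float
    oculomotor: float
    disorientation: float
    total: float


@dataclass(frozen=True)
class IPQScores:
    total: float
    general: float
    spatial: float
    involvement: float
    realism: float


def _as_ratings(resp, n_items: int, lo: int, hi: int, instrument: str) -> list[int]:
    """Normalize a sequence or {item_id: rating} mapping; validate range."""
    if isinstance(resp, Mapping):
        try:
            values = [resp[i] for i in range(1, n_items + 1)]
        except KeyError as err:
            raise ValidationError(
                f"{instrument}: missing rating for item {err.args[0]}"
            ) from err
    else:
        values = list(resp)
    if len(values) != n_items:
        raise ValidationError(
            f"{instrument}: expected {n_items} item ratings, got {len(values)}"
        )
    out = []
    for i, v in enumerate(values, start=1):
        if not float(v).is_integer() or not lo <= int(v) <= hi:
            raise ValidationError(
                f"{instrument}: item {i} rating {v!r} outside {lo}..{hi}"
            )
        out.append(int(v))
    return out


def score_ssq(resp: Sequence[int] | Mapping[int, int]) -> SSQScores:
    """Weighted SSQ subscale and total scores.

    An item belonging to two subscales contributes its rating to both raw
    sums (the instrument's overlap rule); the total uses the unweighted
    subscale sums.
    """
    ratings = _as_ratings(resp, 16, 0, 3, "SSQ")
    raw = {s: 0 for s in SSQ_SUBSCALES}
    for item, rating in zip(_SSQ["items"], ratings):
        for s in item["subscales"]:
            raw[s] += rating
    w = _SSQ["weights"]
    return SSQScores(
        nausea=raw["nausea"] * w["nausea"],
        oculomotor=raw["oculomotor"] * w["oculomotor"],
        disorientation=raw["disorientation"] * w["disorientation"],
        total=sum(raw.values()) * w["total"],
    )


def classify_ssq(total: float) -> str:
    """'actively_ill' iff the total strictly exceeds 100, else 'acceptable'."""
    return "actively_ill" if total > SSQ_ACTIVELY_ILL_THRESHOLD else "acceptable"


def score_ipq(resp: Sequence[int] | Mapping[int, int]) -> IPQScores:
    """iPQ subscale sums and the 14-item total, reverse keying applied."""
    lo, hi = _IPQ["scale"]["min"], _IPQ["scale"]["max"]
    ratings = _as_ratings(resp, 14, lo, hi, "iPQ")
    sums = {"general": 0, "spatial": 0, "involvement": 0, "realism": 0}
    for item, rating in zip(_IPQ["items"], ratings):
        keyed = (lo + hi - rating) if item["reverse"] else rating
        sums[item["category"]] += keyed
    total = sum(sums.values())
    return IPQScores(total=float(total), general=float(sums["general"]),
                     spatial=float(sums["spatial"]),
                     involvement=float(sums["involvement"]),
                     realism=float(sums["realism"]))


def ipq_neutral_reference() -> float:
    """Half the maximum achievable 14-item total (35 on the 1–5 scale)."""
    hi = _IPQ["scale"]["max"]
    return len(_IPQ["items"]) * hi / 2.0


def score_sus(resp: Sequence[int] | Mapping[int, int]) -> float:
    """Brooke SUS composite on 0–100.

    Odd (positively keyed) items contribute rating−1, even items 5−rating;
    the sum of contributions is scaled by 2.5.
    """
    ratings = _as_ratings(resp, 10, 1, 5, "SUS")
    contrib = 0
    for i, rating in enumerate(ratings, start=1):
        contrib += (rating - 1) if i % 2 == 1 else (5 - rating)
    return contrib * 2.5
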