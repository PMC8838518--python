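"""Threshold classification of neonatal vital signs.

Temperature classes follow the WHO staging of neonatal thermal state:
severe hypothermia below 32 °C, moderate hypothermia from 32 to below
36 °C, mild hypothermia from 36 to below 36.5 °C, normothermia from
36.5 to 37.5 °C, hyperthermia above 37.5 °C and severe hyperthermia at
40 °C and above.  Heart-rate classes follow common neonatal guidelines:
bradycardia below 100 bpm (severe below 80) and tachycardia above
200 bpm (severe above 220); the severest matching band wins.  A
central-peripheral temperature difference whose magnitude exceeds 2 °C
flags centralization.

Classes partition the real line: every finite temperature and rate maps
to exactly one label.  No hysteresis is applied to instantaneous labels;
phase-level labels are a majority vote over post-settling samples.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "TempClass",
    "HRClass",
    "PathologyLabel",
    "classify_temperature",
    "classify_hr",
    "classify_cptd",
    "label_phases",
    "PhaseLabel",
]


class TempClass(str, Enum):
    SEVERE_HYPOTHERMIA = "severe_hypothermia"
    MODERATE_HYPOTHERMIA = "moderate_hypothermia"
    MILD_HYPOTHERMIA = "mild_hypothermia"
    NORMOTHERMIA = "normothermia"
    HYPERTHERMIA = "hyperthermia"
    SEVERE_HYPERTHERMIA = "severe_hyperthermia"


class HRClass(str, Enum):
    SEVERE_BRADYCARDIA = "severe_bradycardia"
    BRADYCARDIA = "bradycardia"
    PHYSIOLOGICAL = "physiological"
    TACHYCARDIA = "tachycardia"
    SEVERE_TACHYCARDIA = "severe_tachycardia"


_TEMP_ORDER = list(TempClass)


@dataclass(frozen=True)
class PathologyLabel:
    """Instantaneous classification of one vitals record."""

    timestamp: float
    temp_class: TempClass | None
    hr_class: HRClass | None
    increased_cptd: bool | None  # None when cpTD unavailable


def classify_temperature(t: float) -> TempClass:
    """WHO thermal staging; boundaries 36.5 and 37.5 °C are normothermic."""
    if not math.isfinite(t):
        raise ValueError(f"temperature must be finite, got {t}")
    if t < 32.0:
        return TempClass.SEVERE_HYPOTHERMIA
    if t < 36.0:
        return TempClass.MODERATE_HYPOTHERMIA
    if t < 36.5:
        return TempClass.MILD_HYPOTHERMIA
    if t <= 37.5:
        return TempClass.NORMOTHERMIA
    if t < 40.0:
        return TempClass.HYPERTHERMIA
    return TempClass.SEVERE_HYPERTHERMIA


def classify_hr(hr: float) -> HRClass:
    """Neonatal heart-rate bands; the severest matching band wins."""
    if not math.isfinite(hr):
        raise ValueError(f"heart rate must be finite, got {hr}")
    if hr > 220.0:
        return HRClass.SEVERE_TACHYCARDIA
    if hr > 200.0:
        return HRClass.TACHYCARDIA
    if hr < 80.0:
        return HRClass.SEVERE_BRADYCARDIA
    if hr < 100.0:
        return HRClass.BRADYCARDIA
    return HRClass.PHYSIOLOGICAL


def classify_cptd(cptd: float | None) -> bool | None:
    """True iff |cpTD| strictly exceeds 2 °C; None when unavailable."""
    if cptd is None:
        return None
    if not math.isfinite(cptd):
        raise ValueError(f"cpTD must be finite, got {cptd}")
    return abs(cptd) > 2.0


@dataclass(frozen=True)
class PhaseLabel:
    """Majority classification of one scenario phase."""

    phase: int
    start: float
    end: float
    condition: str
    temp_class: TempClass | None
    hr_class: HRClass | None
    increased_cptd: bool | None
    inconclusive: bool
    n_samples: int


def _majority(items):
    items = [i for i in items if i is not None]
    if not items:
        return None, False
    counts = Counter(items).most_common()
    top, n_top = counts[0]
    tie = len(counts) > 1 and counts[1][1] == n_top
    return top, tie


def label_phases(
    records,
    phase_bounds,
    settling: float = 30.0,
    severe_centralization_cptd: float = 5.0,
) -> list[PhaseLabel]:
    """Label each scenario phase by majority vote over settled samples.

    ``records`` is an iterable of :class:`~neophantom.vitals.VitalsRecord`
    (or anything with ``timestamp``, ``roi_temps``, ``cptd``, ``hr``);
    ``phase_bounds`` the ordered phase boundary times ``[t0, t1, ..., tN]``
    for N phases.  Samples within ``settling`` seconds of a phase start
    are excluded.  Phases shorter than the settling window, or with tied
    majority classes, are flagged inconclusive.

    The condition string mirrors the clinical reading: centralization
    (severe above ``severe_centralization_cptd`` °C median |cpTD|) when
    the cpTD flag carries the majority, otherwise the temperature class
    and, where heart rate is tracked, the heart-rate class.
    """
    records = sorted(records, key=lambda r: r.timestamp)
    labels: list[PhaseLabel] = []
    for k in range(len(phase_bounds) - 1):
        t0, t1 = phase_bounds[k], phase_bounds[k + 1]
        settled = [r for r in records if t0 + settling <= r.timestamp < t1]
        inconclusive = t1 - t0 <= settling or not settled

        chest = [r.roi_temps.get("chest") for r in settled]
        temp_cls = [classify_temperature(t) for t in chest if t is not None]
        hr_cls = [classify_hr(r.hr) for r in settled if r.hr is not None]
        cptd_flags = [classify_cptd(r.cptd) for r in settled if r.cptd is not None]
        cptds = [r.cptd for r in settled if r.cptd is not None]

        temp_major, tie_t = _majority(temp_cls)
        hr_major, tie_h = _majority(hr_cls)
        flag_major, tie_f = _majority(cptd_flags)
        inconclusive = inconclusive or tie_t or tie_h or tie_f

        if flag_major:
            median_mag = float(np.median(np.abs(cptds))) if cptds else 0.0
            condition = (
                "Severe Centralization"
                if median_mag > severe_centralization_cptd
                else "Centralization"
            )
        elif temp_major is not None:
            condition = temp_major.value.replace("_", " ").title()
        elif hr_major is not None:
            condition = hr_major.value.replace("_", " ").title()
        else:
            condition = "Unknown"
            inconclusive = True

        labels.append(
            PhaseLabel(
                phase=k + 1,
                start=float(t0),
                end=float(t1),
                condition=condition,
                temp_class=temp_major,
                hr_class=hr_major,
                increased_cptd=flag_major,
                inconclusive=bool(inconclusive),
                n_samples=len(settled),
            )
        )
    return labels
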