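"""Gain-offset calibration of low-cost thermal cameras.

Low-cost uncooled LWIR microbolometer camera modules read
surface temperatures with an absolute accuracy of only a few °C, and an
infrared inspection window in front of the sensor further skews the
reading — low temperatures are overestimated and high temperatures
underestimated.  Both effects are well captured by an affine correction

    Ts = K1 * Tm + K2

mapping the measured temperature ``Tm`` to the true surface temperature
``Ts``.  ``K1`` and ``K2`` are fitted by ordinary least squares against a
gold-standard reference (a contact probe on an active black-body), which
is treated as exact.  Error statistics are restricted to the clinically
relevant band (30–40 °C by default): only samples whose *reference*
temperature falls in the band contribute.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "CalibrationModel",
    "ErrorStats",
    "fit_calibration",
    "apply_calibration",
    "error_stats",
    "relative_improvement",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Affine temperature correction ``Ts = K1 * Tm + K2``."""

    k1: float
    k2: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.k1) and math.isfinite(self.k2)):
            raise ValueError("calibration coefficients must be finite")
        if self.k1 == 0:
            raise ValueError("gain K1 must be non-zero")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"K1": self.k1, "K2": self.k2}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        d = json.loads(Path(path).read_text())
        return cls(k1=float(d["K1"]), k2=float(d["K2"]))

    def inverse(self, ts: np.ndarray | float) -> np.ndarray | float:
        """Measured temperature a sensor with this response would report."""
        return (ts - self.k2) / self.k1


@dataclass(frozen=True)
class ErrorStats:
    """Band-restricted error statistics of calibrated vs. reference °C.

    ``mae`` is the mean absolute error, ``std`` the standard deviation of
    the signed error, ``max``/``min`` the signed extremes, over the ``n``
    samples whose reference lies inside ``band``.
    """

    mae: float
    std: float
    max: float
    min: float
    band: tuple[float, float]
    n: int

    def as_dict(self) -> dict:
        d = asdict(self)
        d["band"] = list(self.band)
        return d


def fit_calibration(measured, reference) -> CalibrationModel:
    """Least-squares fit of ``Ts = K1 * Tm + K2``.

    Requires at least two distinct measured temperatures; a constant
    measured series leaves the gain unidentifiable and is rejected.
    """
    tm = np.asarray(measured, dtype=float).ravel()
    ts = np.asarray(reference, dtype=float).ravel()
    if tm.size != ts.size:
        raise ValueError("measured and reference must have equal length")
    if tm.size < 2:
        raise ValueError("need at least two calibration pairs")
    if np.ptp(tm) == 0:
        raise ValueError("measured temperatures are constant; gain unidentifiable")
    k1, k2 = np.polynomial.polynomial.polyfit(tm, ts, 1)[::-1]
    return CalibrationModel(k1=float(k1), k2=float(k2))


def apply_calibration(model: CalibrationModel, tm):
    """Elementwise ``Ts = K1 * Tm + K2``."""
    return model.k1 * np.asarray(tm, dtype=float) + model.k2


def error_stats(
    calibrated,
    reference,
    band: tuple[float, float] = (30.0, 40.0),
) -> ErrorStats:
    """Error statistics over samples whose reference lies in ``band``."""
    cal = np.asarray(calibrated, dtype=float).ravel()
    ref = np.asarray(reference, dtype=float).ravel()
    if cal.size != ref.size:
        raise ValueError("calibrated and reference must have equal length")
    lo, hi = band
    if not lo < hi:
        raise ValueError("band low must be < band high")
    mask = (ref >= lo) & (ref <= hi)
    if not mask.any():
        raise ValueError(f"no reference samples inside band {band}")
    err = cal[mask] - ref[mask]
    return ErrorStats(
        mae=float(np.mean(np.abs(err))),
        std=float(np.std(err)),
        max=float(np.max(err)),
        min=float(np.min(err)),
        band=(float(lo), float(hi)),
        n=int(mask.sum()),
    )


def relative_improvement(error_before: float, error_after: float) -> float:
    """Relative error reduction in percent, ``100 * (before - after) / before``."""
    if error_before <= 0:
        raise ValueError("error_before must be > 0")
    return 100.0 * (error_before - error_after) / error_before
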