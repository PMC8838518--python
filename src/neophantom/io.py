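"""Persistence of frames, traces and reports in plain interchange formats.

Thermal frames are stored either as CSV grids of °C values or as 16-bit
PNG counts in centi-°C (value 3500 = 35.00 °C); RGB frames as 8-bit PNG.
Simulated traces go to tidy CSV (time_s, channel, value).
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .regions import RegionId
from .scene import RGBFrame, ThermalFrame

__all__ = [
    "save_thermal_csv",
    "load_thermal_csv",
    "save_thermal_png",
    "load_thermal_png",
    "save_rgb_png",
    "load_rgb_png",
    "traces_to_csv",
]

CENTI = 100.0  # counts per °C in 16-bit thermal PNGs
_PNG_OFFSET = 100.0  # °C; shifts the sensor range into unsigned counts


def save_thermal_csv(frame: ThermalFrame, path: str | Path) -> None:
    np.savetxt(path, frame.values, delimiter=",", fmt="%.4f")


def load_thermal_csv(path: str | Path, camera_id: int = 1, timestamp: float = 0.0) -> ThermalFrame:
    values = np.loadtxt(path, delimiter=",", ndmin=2)
    return ThermalFrame(values=values, camera_id=camera_id, timestamp=timestamp)


def save_thermal_png(frame: ThermalFrame, path: str | Path) -> None:
    counts = np.round((frame.values + _PNG_OFFSET) * CENTI)
    if counts.min() < 0 or counts.max() > 0xFFFF:
        raise ValueError("temperatures outside the 16-bit PNG encoding range")
    iio.imwrite(Path(path), counts.astype(np.uint16))


def load_thermal_png(path: str | Path, camera_id: int = 1, timestamp: float = 0.0) -> ThermalFrame:
    counts = iio.imread(Path(path)).astype(float)
    return ThermalFrame(values=counts / CENTI - _PNG_OFFSET, camera_id=camera_id, timestamp=timestamp)


def save_rgb_png(frame: RGBFrame, path: str | Path) -> None:
    iio.imwrite(Path(path), np.round(frame.values * 255).astype(np.uint8))


def load_rgb_png(path: str | Path, timestamp: float = 0.0, frame_rate: float = 30.0) -> RGBFrame:
    values = iio.imread(Path(path)).astype(float) / 255.0
    return RGBFrame(values=values[..., :3], timestamp=timestamp, frame_rate=frame_rate)


def traces_to_csv(times: np.ndarray, series: dict, path: str | Path) -> None:
    """Tidy CSV export of per-channel traces: time_s, channel, value."""
    rows = []
    for channel, values in series.items():
        name = channel.value if isinstance(channel, RegionId) else str(channel)
        for t, v in zip(times, values):
            rows.append({"time_s": t, "channel": name, "value": v})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.4f")
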