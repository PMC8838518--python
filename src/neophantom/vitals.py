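"""Vital-sign extraction from registered frames.

Six regions of interest — forehead, chest, both hands, both feet — are
constructed from the body-pose keypoints, scaled by the neck-to-mid-hip
distance so the geometry adapts to subject size and camera distance.
From the calibrated thermal mosaic each ROI yields a mean skin
temperature; the central-peripheral temperature difference (cpTD) is the
chest temperature minus the mean of the available peripheral ROIs, an
unspecific early sign of sepsis when it exceeds 2 °C.

Heart rate is extracted by photoplethysmography imaging (PPGI): the mean
red-channel intensity inside the forehead ROI forms a per-frame signal;
major peaks are selected by fractional prominence (rejecting the smaller
diastolic maxima), implausible inter-beat intervals outside 36–300 bpm
are discarded, and the rate is 60 over the mean of the valid intervals
from the trailing 10 s window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .scene import KeypointSet, RGBFrame

__all__ = [
    "ROI",
    "PPGISignal",
    "VitalsRecord",
    "PERIPHERAL_ROIS",
    "rois_from_keypoints",
    "roi_temperature",
    "compute_cptd",
    "extract_ppgi",
    "detect_peaks",
    "estimate_hr",
    "hr_quantization_bound",
]

ROI_NAMES = ("forehead", "chest", "left_hand", "right_hand", "left_foot", "right_foot")
PERIPHERAL_ROIS = ("left_hand", "right_hand", "left_foot", "right_foot")

HR_MIN_BPM = 36.0
HR_MAX_BPM = 300.0


@dataclass(frozen=True)
class ROI:
    """Named half-open pixel rectangle ``[x, x+w) × [y, y+h)``."""

    name: str
    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"ROI {self.name} has non-positive size {self.w}x{self.h}")

    def slice(self) -> tuple[slice, slice]:
        return (slice(self.y, self.y + self.h), slice(self.x, self.x + self.w))

    def clipped(self, frame_size: tuple[int, int]) -> "ROI":
        """Clip to ``(width, height)`` frame bounds."""
        fw, fh = frame_size
        x0, y0 = max(self.x, 0), max(self.y, 0)
        x1, y1 = min(self.x + self.w, fw), min(self.y + self.h, fh)
        if x1 <= x0 or y1 <= y0:
            raise ValueError(f"ROI {self.name} falls entirely outside the frame")
        return ROI(self.name, x0, y0, x1 - x0, y1 - y0)


@dataclass(frozen=True)
class PPGISignal:
    """Per-frame mean red-channel intensity of one ROI."""

    times: np.ndarray
    values: np.ndarray
    source_roi: str = "forehead"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape:
            raise ValueError("times and values must have equal shape")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class VitalsRecord:
    """Extracted vitals at one timestamp.

    ``hr`` is None when no valid inter-beat interval fell in the window;
    ``cptd`` is None when chest or all peripheral ROIs are unavailable.
    """

    timestamp: float
    roi_temps: dict[str, float]
    cptd: float | None
    hr: float | None
    n_valid_intervals: int = 0


def _center_square(name: str, cx: float, cy: float, side: float) -> ROI:
    half = side / 2.0
    return ROI(name, int(round(cx - half)), int(round(cy - half)), int(round(side)), int(round(side)))


def rois_from_keypoints(
    kps: KeypointSet,
    frame_size: tuple[int, int],
    scale_fraction: float = 0.4,
) -> dict[str, ROI]:
    """Build the six measurement ROIs from a keypoint skeleton.

    Square ROIs with side ``scale_fraction`` times the neck-to-mid-hip
    distance: hands on the wrists, feet on the ankles, chest at the
    shoulder/hip centroid, forehead offset from the nose by half a side
    along the neck→nose axis (away from the body).  Keypoints with zero
    confidence yield missing ROIs; downstream statistics use whatever is
    available.  Raises when the torso keypoints needed for the scale are
    missing.
    """
    neck = kps.get("neck")
    hips = [p for p in (kps.get("left_hip"), kps.get("right_hip")) if p is not None]
    if neck is None or not hips:
        raise ValueError("torso keypoints (neck, hip) required to scale ROIs")
    mid_hip = tuple(np.mean(hips, axis=0))
    torso_len = math.dist(neck, mid_hip)
    if torso_len <= 0:
        raise ValueError("degenerate torso: neck coincides with mid-hip")
    side = scale_fraction * torso_len

    rois: dict[str, ROI] = {}

    shoulders = [p for p in (kps.get("left_shoulder"), kps.get("right_shoulder")) if p is not None]
    if shoulders:
        pts = shoulders + hips
        cx, cy = np.mean([p[0] for p in pts]), np.mean([p[1] for p in pts])
        rois["chest"] = _center_square("chest", cx, cy, side)

    nose = kps.get("nose")
    if nose is not None:
        ux, uy = nose[0] - neck[0], nose[1] - neck[1]
        norm = math.hypot(ux, uy)
        if norm > 0:
            cx = nose[0] + 0.5 * side * ux / norm
            cy = nose[1] + 0.5 * side * uy / norm
            rois["forehead"] = _center_square("forehead", cx, cy, side)

    for roi_name, kp_name in (
        ("left_hand", "left_wrist"),
        ("right_hand", "right_wrist"),
        ("left_foot", "left_ankle"),
        ("right_foot", "right_ankle"),
    ):
        p = kps.get(kp_name)
        if p is not None:
            rois[roi_name] = _center_square(roi_name, p[0], p[1], side)

    return {name: roi.clipped(frame_size) for name, roi in rois.items()}


def roi_temperature(mosaic_values: np.ndarray, roi: ROI) -> float | None:
    """Mean of valid (non-NaN) calibrated pixels inside the ROI.

    Returns None when every pixel in the ROI is invalid (e.g. the ROI
    falls outside both thermal footprints).
    """
    patch = mosaic_values[roi.slice()]
    if patch.size == 0:
        return None
    valid = patch[~np.isnan(patch)]
    if valid.size == 0:
        return None
    return float(valid.mean())


def compute_cptd(roi_temps: dict[str, float | None]) -> float | None:
    """Central-peripheral temperature difference.

    Chest temperature minus the mean over the *available* peripheral
    ROIs (hands and feet).  None when the chest or every peripheral is
    unavailable.
    """
    chest = roi_temps.get("chest")
    if chest is None:
        return None
    periph = [roi_temps[n] for n in PERIPHERAL_ROIS if roi_temps.get(n) is not None]
    if not periph:
        return None
    return float(chest - np.mean(periph))


def extract_ppgi(frames, head_roi: ROI) -> PPGISignal:
    """Per-frame spatial mean of the red channel over the head ROI."""
    times, values = [], []
    for frame in frames:
        patch = frame.values[head_roi.slice() + (0,)]
        if patch.size == 0:
            raise ValueError("head ROI empty in frame")
        times.append(frame.timestamp)
        values.append(float(patch.mean()))
    if not times:
        raise ValueError("empty frame sequence")
    return PPGISignal(times=np.array(times), values=np.array(values), source_roi=head_roi.name)


def detect_peaks(
    signal: PPGISignal,
    prominence_fraction: float = 0.5,
    min_rate: float = HR_MIN_BPM,
    max_rate: float = HR_MAX_BPM,
) -> np.ndarray:
    """Times of the major peaks of a PPGI signal.

    Local maxima are kept only when their prominence reaches
    ``prominence_fraction`` of the signal's full range — this rejects the
    smaller diastolic maxima and noise bumps — and peaks closer together
    than the 60/``max_rate`` refractory interval are pruned (highest
    first).  A flat signal has no peaks.
    """
    if signal.values.size < 3:
        raise ValueError("need at least 3 samples for peak detection")
    rng_ = float(np.ptp(signal.values))
    if rng_ == 0:
        return np.array([])
    fs = 1.0 / float(np.median(np.diff(signal.times)))
    distance = max(1, int(round(60.0 / max_rate * fs)))
    idx, _ = find_peaks(
        signal.values,
        prominence=prominence_fraction * rng_,
        distance=distance,
    )
    return signal.times[idx]


def estimate_hr(
    peak_times: np.ndarray,
    now: float,
    window: float = 10.0,
    min_rate: float = HR_MIN_BPM,
    max_rate: float = HR_MAX_BPM,
) -> tuple[float | None, int]:
    """Windowed heart-rate estimate from detected peak times.

    Inter-peak intervals ending within ``(now - window, now]`` are kept;
    intervals implying a rate outside ``[min_rate, max_rate]`` bpm are
    discarded as noise.  The estimate is 60 over the mean of the valid
    intervals — None (undefined) when there are none.  Returns
    ``(hr_bpm_or_None, n_valid_intervals)``.
    """
    peaks = np.asarray(peak_times, dtype=float)
    if peaks.size < 2:
        return None, 0
    intervals = np.diff(peaks)
    ends = peaks[1:]
    in_window = (ends > now - window) & (ends <= now)
    valid = in_window & (intervals >= 60.0 / max_rate) & (intervals <= 60.0 / min_rate)
    n = int(valid.sum())
    if n == 0:
        return None, 0
    return float(60.0 / intervals[valid].mean()), n


def hr_quantization_bound(rate_bpm: float, fs: float, n_intervals: int) -> float:
    """Worst-case bpm error from frame-grid quantization of peak times.

    With peaks quantized to the frame grid, the summed span of ``n``
    intervals is off by at most one frame period, bounding the estimate
    error by ``60 f² / (60 fs n - f)`` for true rate ``f`` and frame rate
    ``fs``.
    """
    return 60.0 * rate_bpm**2 / (60.0 * fs * n_intervals - rate_bpm)
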