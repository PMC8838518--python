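"""Synthetic multi-modal scene rendering.

Stands in for the physical cameras and the pretrained pose network: a
canonical scene canvas holds the phantom's 13 heating regions as pixel
masks plus a ground-truth keypoint skeleton.  From per-region skin
temperatures it renders

* two overlapping low-resolution thermal views, each distorted by the
  *inverse* of its camera's true gain-offset response (so the pipeline's
  calibration has something real to undo), plus Gaussian sensor noise
  and quantization;
* an RGB stream whose red channel inside the head region is modulated by
  the PPG waveform (the phantom's red LEDs);
* the keypoint set, optionally jittered, replacing the pose estimator.

Pixel convention everywhere: 0-based, x right / y down, half-open
rectangles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .calibration import CalibrationModel
from .regions import RegionId
from .registration import Homography

__all__ = [
    "KeypointSet",
    "BodyLayout",
    "ThermalSensorModel",
    "ThermalFrame",
    "RGBFrame",
    "default_layout",
    "default_view_transforms",
    "render_thermal_pair",
    "render_rgb",
    "emit_keypoints",
]

KEYPOINT_NAMES = (
    "nose",
    "neck",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)


@dataclass(frozen=True)
class KeypointSet:
    """Named skeleton points: name → (x, y, confidence in [0, 1])."""

    points: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        for name, (x, y, c) in self.points.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"confidence of {name} outside [0, 1]: {c}")

    def get(self, name: str) -> tuple[float, float] | None:
        """Coordinates of a keypoint, or None if absent / zero confidence."""
        p = self.points.get(name)
        if p is None or p[2] <= 0:
            return None
        return (p[0], p[1])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {k: {"x": v[0], "y": v[1], "confidence": v[2]} for k, v in self.points.items()},
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "KeypointSet":
        d = json.loads(Path(path).read_text())
        return cls({k: (v["x"], v["y"], v["confidence"]) for k, v in d.items()})


@dataclass(frozen=True)
class BodyLayout:
    """Region masks and ground-truth keypoints in canvas coordinates."""

    region_masks: dict[RegionId, np.ndarray]  # bool, (H, W)
    keypoints: KeypointSet
    canvas_size: tuple[int, int]  # (width, height)

    def __post_init__(self) -> None:
        w, h = self.canvas_size
        stack = None
        for region, mask in self.region_masks.items():
            if mask.shape != (h, w):
                raise ValueError(f"mask for {region} has shape {mask.shape}, canvas is {(h, w)}")
            stack = mask.astype(int) if stack is None else stack + mask.astype(int)
        if stack is not None and stack.max() > 1:
            raise ValueError("region masks overlap")

    @property
    def head_mask(self) -> np.ndarray:
        return self.region_masks[RegionId.HEAD_FRONT] | self.region_masks[RegionId.HEAD_BACK]

    def temperature_field(
        self, skin_temps: dict[RegionId, float], ambient: float = 30.0
    ) -> np.ndarray:
        """Canvas-resolution temperature map; background at ambient."""
        w, h = self.canvas_size
        field_ = np.full((h, w), float(ambient))
        for region, mask in self.region_masks.items():
            if region in skin_temps:
                field_[mask] = float(skin_temps[region])
        return field_


@dataclass(frozen=True)
class ThermalSensorModel:
    """True affine response of one thermal camera plus its noise floor.

    A camera with true calibration ``Ts = K1_true * Tm + K2_true`` reports
    ``Tm = (Ts - K2_true) / K1_true`` for a surface at ``Ts``; Gaussian
    noise and quantization (default 0.01 °C, below the sensor's 0.05 K
    thermal sensitivity) are applied on top.
    """

    k1_true: float = 1.82
    k2_true: float = -20.18
    noise_sigma: float = 0.0
    quantization: float = 0.01
    resolution: tuple[int, int] = (160, 120)  # (width, height)
    frame_rate: float = 8.7

    def __post_init__(self) -> None:
        if self.k1_true == 0:
            raise ValueError("true gain must be non-zero")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def true_model(self) -> CalibrationModel:
        return CalibrationModel(k1=self.k1_true, k2=self.k2_true)

    def measure(self, ts: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        """Measured temperature for true surface temperature(s) ``ts``."""
        tm = (np.asarray(ts, dtype=float) - self.k2_true) / self.k1_true
        if self.noise_sigma > 0:
            if rng is None:
                raise ValueError("rng required when noise_sigma > 0")
            tm = tm + rng.normal(0.0, self.noise_sigma, size=tm.shape)
        if self.quantization > 0:
            tm = np.round(tm / self.quantization) * self.quantization
        return tm


@dataclass(frozen=True)
class ThermalFrame:
    """One measured-temperature grid from a thermal camera."""

    values: np.ndarray  # (H, W) °C, measured (uncalibrated)
    camera_id: int
    timestamp: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.values).all():
            raise ValueError("thermal frame contains non-finite values")


@dataclass(frozen=True)
class RGBFrame:
    """One RGB frame, channel order (R, G, B), intensities in [0, 1]."""

    values: np.ndarray  # (H, W, 3)
    timestamp: float
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 3 or v.shape[2] != 3:
            raise ValueError("RGB frame must be (H, W, 3)")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("intensities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# default scene geometry
# ---------------------------------------------------------------------------


def default_layout(canvas_size: tuple[int, int] = (640, 360)) -> BodyLayout:
    """Phantom lying horizontally, head at the left of the canvas.

    All geometry is defined in a reference 640×360 canvas and scaled by
    the requested size.  Region interiors are generous around the spots
    where the ROIs land, so the warped thermal mosaic samples uniform
    temperatures away from region borders.
    """
    w, h = canvas_size
    sx, sy = w / 640.0, h / 360.0

    def pt(x: float, y: float) -> tuple[float, float]:
        return (x * sx, y * sy)

    yy, xx = np.mgrid[0:h, 0:w]

    def rect(x0: float, y0: float, x1: float, y1: float) -> np.ndarray:
        return (xx >= x0 * sx) & (xx < x1 * sx) & (yy >= y0 * sy) & (yy < y1 * sy)

    cxh, cyh = 115 * sx, 180 * sy
    rx, ry = 62 * sx, 62 * sy
    head = ((xx - cxh) / rx) ** 2 + ((yy - cyh) / ry) ** 2 < 1.0

    masks: dict[RegionId, np.ndarray] = {
        RegionId.HEAD_FRONT: head & (xx < cxh),
        RegionId.HEAD_BACK: head & (xx >= cxh),
        RegionId.TORSO_UPPER: rect(180, 130, 237, 230),
        RegionId.TORSO_MID: rect(237, 130, 294, 230),
        RegionId.TORSO_LOWER: rect(294, 130, 350, 230),
        RegionId.LEFT_ARM_UPPER: rect(170, 90, 210, 130),
        RegionId.LEFT_ARM_LOWER: rect(140, 0, 240, 90),
        RegionId.RIGHT_ARM_UPPER: rect(170, 230, 210, 270),
        RegionId.RIGHT_ARM_LOWER: rect(140, 270, 240, 360),
        RegionId.LEFT_LEG_UPPER: rect(320, 90, 360, 130),
        RegionId.LEFT_LEG_LOWER: rect(300, 0, 380, 90),
        RegionId.RIGHT_LEG_UPPER: rect(320, 230, 360, 270),
        RegionId.RIGHT_LEG_LOWER: rect(300, 270, 380, 360),
    }

    kp = {
        "nose": (*pt(130, 180), 1.0),
        "neck": (*pt(180, 180), 1.0),
        "left_shoulder": (*pt(190, 140), 1.0),
        "right_shoulder": (*pt(190, 220), 1.0),
        "left_elbow": (*pt(190, 90), 1.0),
        "right_elbow": (*pt(190, 270), 1.0),
        "left_wrist": (*pt(190, 45), 1.0),
        "right_wrist": (*pt(190, 315), 1.0),
        "left_hip": (*pt(340, 140), 1.0),
        "right_hip": (*pt(340, 220), 1.0),
        "left_knee": (*pt(340, 90), 1.0),
        "right_knee": (*pt(340, 270), 1.0),
        "left_ankle": (*pt(340, 45), 1.0),
        "right_ankle": (*pt(340, 315), 1.0),
    }
    return BodyLayout(region_masks=masks, keypoints=KeypointSet(kp), canvas_size=canvas_size)


def default_view_transforms(
    canvas_size: tuple[int, int] = (640, 360),
    sensor_resolution: tuple[int, int] = (160, 120),
    overlap_fraction: float = 0.15,
) -> tuple[Homography, Homography]:
    """Canvas→sensor homographies for the two thermal views.

    Horizontal split: camera 1 sees the left part of the canvas (head and
    upper body), camera 2 the right part, overlapping by
    ``overlap_fraction`` of the canvas width.
    """
    w, h = canvas_size
    sw, sh = sensor_resolution
    view_w = w * (1 + overlap_fraction) / 2.0
    t1 = Homography.scale_translate(sw / view_w, sh / h, 0.0, 0.0)
    x0 = w - view_w
    t2 = Homography.scale_translate(sw / view_w, sh / h, -x0 * sw / view_w, 0.0)
    return t1, t2


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_thermal_pair(
    skin_temps: dict[RegionId, float],
    layout: BodyLayout,
    sensor: ThermalSensorModel,
    view_transforms: tuple[Homography, Homography] | None = None,
    seed: int = 0,
    timestamp: float = 0.0,
    ambient: float = 30.0,
) -> tuple[ThermalFrame, ThermalFrame]:
    """Render the two thermal views of the scene.

    Each camera sees the canvas through its canvas→sensor projective
    view; every sensor pixel reads the temperature of the canvas point it
    images (nearest canvas pixel), passed through the sensor's inverse
    response plus noise and quantization.  Background is at ``ambient``
    (the incubator set point, 30 °C by default).
    """
    if view_transforms is None:
        view_transforms = default_view_transforms(layout.canvas_size, sensor.resolution)
    field_ = layout.temperature_field(skin_temps, ambient=ambient)
    w, h = layout.canvas_size
    sw, sh = sensor.resolution
    rng = np.random.default_rng(seed)

    frames = []
    for cam_id, view in zip((1, 2), view_transforms):
        inv = view.inverse()
        ys, xs = np.mgrid[0:sh, 0:sw]
        pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        src = inv.apply(pts)
        cx = np.clip(np.rint(src[:, 0]).astype(int), 0, w - 1)
        cy = np.clip(np.rint(src[:, 1]).astype(int), 0, h - 1)
        ts = field_[cy, cx].reshape(sh, sw)
        tm = sensor.measure(ts, rng=rng if sensor.noise_sigma > 0 else None)
        frames.append(ThermalFrame(values=tm, camera_id=cam_id, timestamp=timestamp))
    return frames[0], frames[1]


def render_rgb(
    ppg_value: float,
    layout: BodyLayout,
    baseline: float = 0.5,
    modulation_depth: float = 0.2,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    timestamp: float = 0.0,
    frame_rate: float = 30.0,
    background: tuple[float, float, float] = (0.2, 0.2, 0.25),
    body_color: tuple[float, float, float] = (0.5, 0.35, 0.3),
) -> RGBFrame:
    """Render one RGB frame with the head's red channel PPG-modulated.

    Red channel inside the head region = ``baseline + modulation_depth *
    ppg_value`` plus optional Gaussian pixel noise (clipped to [0, 1]);
    everything else is constant.
    """
    if baseline < 0 or modulation_depth < 0 or baseline + modulation_depth > 1.0:
        raise ValueError("baseline + modulation_depth must stay within [0, 1]")
    w, h = layout.canvas_size
    values = np.empty((h, w, 3), dtype=np.float32)
    values[..., 0] = background[0]
    values[..., 1] = background[1]
    values[..., 2] = background[2]
    body = np.zeros((h, w), dtype=bool)
    for mask in layout.region_masks.values():
        body |= mask
    for c in range(3):
        values[..., c][body] = body_color[c]

    head = layout.head_mask
    red = baseline + modulation_depth * float(ppg_value)
    if noise_sigma > 0:
        if seed is None:
            raise ValueError("seed required when noise_sigma > 0")
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sigma, size=int(head.sum()))
        values[..., 0][head] = np.clip(red + noise, 0.0, 1.0)
    else:
        values[..., 0][head] = red
    return RGBFrame(values=values, timestamp=timestamp, frame_rate=frame_rate)


class RGBRenderer:
    """Frame-sequence renderer caching the static parts of the scene.

    Functionally identical to :func:`render_rgb` but reuses the base
    frame and head-mask indexing across frames, which matters when
    rendering minutes of 30 fps video.
    """

    def __init__(
        self,
        layout: BodyLayout,
        baseline: float = 0.5,
        modulation_depth: float = 0.2,
        noise_sigma: float = 0.0,
        seed: int | None = None,
        frame_rate: float = 30.0,
        background: tuple[float, float, float] = (0.2, 0.2, 0.25),
        body_color: tuple[float, float, float] = (0.5, 0.35, 0.3),
    ) -> None:
        if baseline < 0 or modulation_depth < 0 or baseline + modulation_depth > 1.0:
            raise ValueError("baseline + modulation_depth must stay within [0, 1]")
        self.layout = layout
        self.baseline = baseline
        self.modulation_depth = modulation_depth
        self.noise_sigma = noise_sigma
        self.frame_rate = frame_rate
        self._rng = np.random.default_rng(seed) if noise_sigma > 0 else None
        if noise_sigma > 0 and seed is None:
            raise ValueError("seed required when noise_sigma > 0")

        w, h = layout.canvas_size
        base = np.empty((h, w, 3), dtype=np.float32)
        for c in range(3):
            base[..., c] = background[c]
        body = np.zeros((h, w), dtype=bool)
        for mask in layout.region_masks.values():
            body |= mask
        for c in range(3):
            base[..., c][body] = body_color[c]
        self._base = base
        self._head = layout.head_mask
        self._n_head = int(self._head.sum())

    def render(self, ppg_value: float, timestamp: float) -> RGBFrame:
        values = self._base.copy()
        red = self.baseline + self.modulation_depth * float(ppg_value)
        if self._rng is not None:
            noise = self._rng.normal(0.0, self.noise_sigma, size=self._n_head)
            values[..., 0][self._head] = np.clip(red + noise, 0.0, 1.0)
        else:
            values[..., 0][self._head] = red
        return RGBFrame(values=values, timestamp=timestamp, frame_rate=self.frame_rate)

    def frames(self, ppg_samples: np.ndarray, t0: float = 0.0):
        """Yield one frame per PPG sample at the renderer's frame rate."""
        for i, v in enumerate(np.asarray(ppg_samples, dtype=float)):
            yield self.render(v, t0 + i / self.frame_rate)


def emit_keypoints(
    layout: BodyLayout,
    jitter_sigma: float = 0.0,
    seed: int = 0,
) -> KeypointSet:
    """Ground-truth keypoints with optional Gaussian positional jitter.

    Replaces the pose-estimation network.  A jittered point pushed off
    the canvas gets confidence 0 (treated as missing downstream).
    """
    if jitter_sigma < 0:
        raise ValueError("jitter_sigma must be >= 0")
    if jitter_sigma == 0:
        return layout.keypoints
    rng = np.random.default_rng(seed)
    w, h = layout.canvas_size
    out = {}
    for name, (x, y, c) in layout.keypoints.points.items():
        jx, jy = x + rng.normal(0, jitter_sigma), y + rng.normal(0, jitter_sigma)
        conf = c if (0 <= jx < w and 0 <= jy < h) else 0.0
        out[name] = (jx, jy, conf)
    return KeypointSet(out)
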