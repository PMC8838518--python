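"""Scenario configuration and end-to-end experiment runners.

A scenario is the machine-readable form of a validation protocol: an
ordered list of temperature phases (per-region targets and durations)
and heart-rate phases (target rate, walk parameters, duration), plus the
sensor models and all seeds.  Two runners reproduce the two validation
experiments:

* :func:`run_calibration_experiment` — sweeps a simulated active
  reference body through 26–45 °C, measures it with both thermal
  cameras, fits the gain-offset calibration on camera 1 and validates on
  camera 2, reporting band-restricted error statistics.

* :func:`run_pathology_experiment` — the full chain: simulate ground
  truth, render frames, calibrate, register and mosaic the thermal
  views, extract ROI temperatures / cpTD / heart rate, classify, and
  label the phases.  Deterministic under fixed seeds.

Processing order per frame: the gain-offset correction is applied to the
raw thermal frames first, then registration and mosaicking; ROIs come
from the RGB-side keypoints; temperatures are read from the corrected,
transformed mosaic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationModel, ErrorStats, apply_calibration, error_stats, fit_calibration
from .pathology import PhaseLabel, label_phases
from .phantom import (
    HRProfile,
    HRTrace,
    TemperaturePhase,
    TemperatureProfile,
    generate_ppg,
    simulate_hr,
    simulate_temperature,
    skin_temperature,
)
from .regions import (
    ALL_REGIONS,
    HEAD_REGIONS,
    LIMB_REGIONS,
    TORSO_REGIONS,
    RegionId,
)
from .registration import (
    CorrespondenceSet,
    Homography,
    estimate_homography,
    mosaic,
    upscale_nearest,
    upscale_transform,
    warp_frame,
)
from .scene import (
    BodyLayout,
    RGBRenderer,
    ThermalSensorModel,
    default_layout,
    default_view_transforms,
    emit_keypoints,
    render_thermal_pair,
)
from .vitals import (
    PPGISignal,
    VitalsRecord,
    compute_cptd,
    detect_peaks,
    estimate_hr,
    extract_ppgi,
    roi_temperature,
    rois_from_keypoints,
)

__all__ = [
    "ScenarioConfig",
    "RunReport",
    "expand_targets",
    "view_correspondences",
    "ThermalPipeline",
    "calibrate_sensor",
    "run_calibration_experiment",
    "run_hr_pipeline",
    "run_pathology_experiment",
    "table_style_temperature_scenario",
    "table_style_hr_scenario",
]

# high-gain operating range of the thermal module, °C
SENSOR_RANGE = (-10.0, 140.0)

_GROUPS: dict[str, tuple[RegionId, ...]] = {
    "head": HEAD_REGIONS,
    "torso": TORSO_REGIONS,
    "limbs": LIMB_REGIONS,
    "all": ALL_REGIONS,
}


def expand_targets(targets: dict[str, float]) -> dict[RegionId, float]:
    """Expand group keys (head/torso/limbs/all) and region names to regions.

    Group keys are applied first so a specific region can override its
    group within the same mapping.
    """
    out: dict[RegionId, float] = {}
    for key, value in targets.items():
        if key in _GROUPS:
            for r in _GROUPS[key]:
                out[r] = float(value)
    for key, value in targets.items():
        if key not in _GROUPS:
            out[RegionId(key)] = float(value)
    return out


@dataclass
class ScenarioConfig:
    """Complete, serializable description of one experiment run.

    Temperature phase maps may use region names or the group keys
    ``head``, ``torso``, ``limbs``, ``all``.  All randomness derives from
    ``seed``; identical configs give byte-identical outputs.
    """

    name: str = "scenario"
    temperature_phases: list[dict] = field(default_factory=list)
    hr_phases: list[dict] = field(default_factory=list)
    initial_set: dict[str, float] = field(default_factory=lambda: {"all": 37.0})
    update_interval: float = 30.0
    max_heat_rate: float = 1.0  # °C/min
    skin_tau: float = 60.0  # s; 0 = skin follows set temperature exactly
    ambient: float = 30.0
    canvas_size: tuple[int, int] = (320, 180)
    sensor: dict = field(default_factory=dict)  # ThermalSensorModel overrides
    thermal_interval: float = 10.0  # s between processed thermal frames
    rgb_frame_rate: float = 30.0
    rgb_baseline: float = 0.6
    rgb_modulation_depth: float = 0.2
    rgb_noise_sigma: float = 0.0
    keypoint_jitter: float = 0.0
    upscale_factor: int = 4
    ransac_threshold: float = 2.0
    ransac_max_iter: int = 1000
    settling: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.canvas_size = tuple(self.canvas_size)  # type: ignore[assignment]

    def sensor_model(self, **overrides) -> ThermalSensorModel:
        kw = dict(self.sensor)
        if "resolution" in kw:
            kw["resolution"] = tuple(kw["resolution"])
        kw.update(overrides)
        return ThermalSensorModel(**kw)

    # --- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["canvas_size"] = list(self.canvas_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    # --- derived -----------------------------------------------------------

    def temperature_profile(self) -> TemperatureProfile:
        phases = tuple(
            TemperaturePhase(targets=expand_targets(p["targets"]), duration=float(p["duration"]))
            for p in self.temperature_phases
        )
        return TemperatureProfile(
            phases=phases,
            initial_set=expand_targets(self.initial_set),
            max_heat_rate=self.max_heat_rate,
            update_interval=self.update_interval,
        )

    def hr_profiles(self) -> list[tuple[HRProfile, float]]:
        out = []
        for p in self.hr_phases:
            profile = HRProfile(
                hrt=float(p["hrt"]),
                rmax=int(p.get("rmax", 0)),
                bound=float(p.get("bound", 10.0)),
                update_interval=float(p.get("update_interval", 5.0)),
            )
            out.append((profile, float(p["duration"])))
        return out


def _subseed(seed: int, k: int) -> int:
    """Deterministic 31-bit sub-seed #k of a master seed."""
    return int(np.random.SeedSequence(seed).generate_state(k + 1)[k] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# registration setup
# ---------------------------------------------------------------------------


def view_correspondences(
    view: Homography,
    upscale_factor: int,
    sensor_resolution: tuple[int, int],
    n_grid: tuple[int, int] = (4, 3),
    margin: int = 5,
) -> CorrespondenceSet:
    """Point correspondences from an upscaled thermal view to the canvas.

    Plays the role of the ten manually clicked point pairs: a grid of
    points on the sensor is mapped to upscaled-frame coordinates (source)
    and, through the known view geometry, to canvas coordinates
    (destination).
    """
    sw, sh = sensor_resolution
    xs = np.linspace(margin, sw - 1 - margin, n_grid[0])
    ys = np.linspace(margin, sh - 1 - margin, n_grid[1])
    gx, gy = np.meshgrid(xs, ys)
    sensor_pts = np.column_stack([gx.ravel(), gy.ravel()])
    src = upscale_transform(upscale_factor).apply(sensor_pts)
    dst = view.inverse().apply(sensor_pts)
    return CorrespondenceSet(src=src, dst=dst)


class ThermalPipeline:
    """Per-frame thermal processing: correct, upscale, warp, mosaic.

    Gain-offset correction is applied to the raw measured frames before
    registration; the two corrected views are upscaled (nearest
    neighbour), warped into the canvas/RGB geometry with the estimated
    homographies, and mosaicked with camera-1 precedence in the overlap.
    """

    def __init__(
        self,
        layout: BodyLayout,
        calibration: CalibrationModel,
        view_transforms: tuple[Homography, Homography],
        sensor_resolution: tuple[int, int] = (160, 120),
        upscale_factor: int = 4,
        ransac_threshold: float = 2.0,
        ransac_max_iter: int = 1000,
        seed: int = 0,
    ) -> None:
        self.layout = layout
        self.calibration = calibration
        self.upscale_factor = upscale_factor
        self.homographies = []
        for i, view in enumerate(view_transforms):
            corr = view_correspondences(view, upscale_factor, sensor_resolution)
            h, _ = estimate_homography(
                corr, ransac_threshold=ransac_threshold, max_iter=ransac_max_iter,
                seed=_subseed(seed, i),
            )
            self.homographies.append(h)

    def process(self, frame1, frame2) -> np.ndarray:
        """Calibrated canvas-geometry mosaic from one raw thermal pair."""
        w, h = self.layout.canvas_size
        warped = []
        for frame, hom in zip((frame1, frame2), self.homographies):
            corrected = apply_calibration(self.calibration, frame.values)
            up = upscale_nearest(corrected, self.upscale_factor)
            warped.append(warp_frame(up, hom, output_size=(h, w)))
        return mosaic(warped[0], warped[1])


# ---------------------------------------------------------------------------
# calibration experiment
# ---------------------------------------------------------------------------


def _reference_sweep(n: int, low: float = 26.0, high: float = 45.0) -> np.ndarray:
    """Triangular reference-body sweep: heat low→high, cool back down."""
    half = n // 2
    up = np.linspace(low, high, half)
    down = np.linspace(high, low, n - half)
    return np.concatenate([up, down])


def calibrate_sensor(
    sensor: ThermalSensorModel,
    n_samples: int = 400,
    seed: int = 0,
    sweep: tuple[float, float] = (26.0, 45.0),
) -> CalibrationModel:
    """Fit a gain-offset calibration from a simulated reference sweep."""
    ref = _reference_sweep(n_samples, *sweep)
    tm = sensor.measure(ref, rng=np.random.default_rng(seed) if sensor.noise_sigma > 0 else None)
    return fit_calibration(tm, ref)


def run_calibration_experiment(
    sensor1: ThermalSensorModel,
    sensor2: ThermalSensorModel | None = None,
    n_samples: int = 1000,
    band: tuple[float, float] = (30.0, 40.0),
    sweep: tuple[float, float] = (26.0, 45.0),
    seed: int = 0,
) -> tuple[CalibrationModel, ErrorStats, ErrorStats]:
    """Fit on camera 1, validate on camera 2, report band statistics.

    Both cameras observe the same simulated active-reference sweep
    (independent noise realizations).  Returns the fitted model and the
    (fitting, validation) error statistics restricted to ``band``.
    """
    lo, hi = sweep
    if lo < SENSOR_RANGE[0] or hi > SENSOR_RANGE[1]:
        raise ValueError(f"sweep {sweep} outside sensor range {SENSOR_RANGE}")
    if sensor2 is None:
        sensor2 = sensor1
    ref = _reference_sweep(n_samples, *sweep)
    rng1 = np.random.default_rng(_subseed(seed, 0))
    rng2 = np.random.default_rng(_subseed(seed, 1))
    tm1 = sensor1.measure(ref, rng=rng1 if sensor1.noise_sigma > 0 else None)
    tm2 = sensor2.measure(ref, rng=rng2 if sensor2.noise_sigma > 0 else None)
    model = fit_calibration(tm1, ref)
    stats_fit = error_stats(apply_calibration(model, tm1), ref, band=band)
    stats_val = error_stats(apply_calibration(model, tm2), ref, band=band)
    return model, stats_fit, stats_val


# ---------------------------------------------------------------------------
# full pathology experiment
# ---------------------------------------------------------------------------


@dataclass
class RunReport:
    """Outputs of one full scenario run; every number is recomputable
    from the persisted CSV intermediates."""

    config: ScenarioConfig
    vitals_csv: Path | None
    hr_csv: Path | None
    temperature_phase_labels: list[PhaseLabel]
    hr_phase_labels: list[PhaseLabel]
    hr_mae_per_phase: list[float | None]
    hr_mae_overall: float | None
    calibration_model: CalibrationModel | None
    calibration_stats: ErrorStats | None

    def phase_table(self) -> pd.DataFrame:
        rows = [
            {
                "experiment": kind,
                "phase": lab.phase,
                "condition": lab.condition,
                "cptd_gt_2C": {True: "Yes", False: "No", None: ""}[lab.increased_cptd],
                "inconclusive": lab.inconclusive,
            }
            for kind, labs in (
                ("temperature", self.temperature_phase_labels),
                ("hr", self.hr_phase_labels),
            )
            for lab in labs
        ]
        return pd.DataFrame(rows)


def _concat_hr_trace(profiles: list[tuple[HRProfile, float]], seed: int) -> tuple[HRTrace, list[float]]:
    """Concatenate per-phase heart-rate walks into one trace.

    Returns the trace and the phase boundary times [t0, ..., tN].
    """
    times, values = [], []
    bounds = [0.0]
    offset = 0.0
    for k, (profile, duration) in enumerate(profiles):
        tr = simulate_hr(profile, duration, seed=_subseed(seed, k))
        keep = tr.times < duration  # phase owns [offset, offset + duration)
        times.append(tr.times[keep] + offset)
        values.append(tr.values[keep])
        offset += duration
        bounds.append(offset)
    return HRTrace(times=np.concatenate(times), values=np.concatenate(values)), bounds


def run_hr_pipeline(
    config: ScenarioConfig,
    layout: BodyLayout | None = None,
) -> tuple[pd.DataFrame, HRTrace, list[float]]:
    """Simulate, render and extract the heart rate for the HR phases.

    Returns a frame-rate DataFrame (t_s, hr_set, hr_est, n_valid_intervals;
    undefined estimates as NaN), the ground-truth set-rate trace and the
    phase boundaries.
    """
    profiles = config.hr_profiles()
    if not profiles:
        return pd.DataFrame(columns=["t_s", "hr_set", "hr_est", "n_valid_intervals"]), None, []
    if layout is None:
        layout = default_layout(config.canvas_size)

    trace, bounds = _concat_hr_trace(profiles, seed=_subseed(config.seed, 10))
    duration = bounds[-1]
    fps = config.rgb_frame_rate
    ppg = generate_ppg(trace, duration, sample_rate=fps)

    renderer = RGBRenderer(
        layout,
        baseline=config.rgb_baseline,
        modulation_depth=config.rgb_modulation_depth,
        noise_sigma=config.rgb_noise_sigma,
        seed=_subseed(config.seed, 11) if config.rgb_noise_sigma > 0 else None,
        frame_rate=fps,
    )
    kps = emit_keypoints(layout, config.keypoint_jitter, seed=_subseed(config.seed, 12))
    rois = rois_from_keypoints(kps, layout.canvas_size)
    signal = extract_ppgi(renderer.frames(ppg.samples), rois["forehead"])

    peaks = detect_peaks(signal)
    hr_est = np.full(signal.times.size, np.nan)
    n_valid = np.zeros(signal.times.size, dtype=int)
    for i, t in enumerate(signal.times):
        hr, n = estimate_hr(peaks, now=t)
        if hr is not None:
            hr_est[i] = hr
            n_valid[i] = n
    df = pd.DataFrame(
        {
            "t_s": signal.times,
            "hr_set": np.asarray(trace.at(signal.times), dtype=float),
            "hr_est": hr_est,
            "n_valid_intervals": n_valid,
        }
    )
    return df, trace, bounds


def hr_mae(df: pd.DataFrame, bounds: list[float], settling: float = 30.0) -> tuple[list[float | None], float | None]:
    """Per-phase and overall MAE of the HR estimate vs. the set rate.

    Samples within ``settling`` seconds of each phase start and undefined
    estimates are excluded (error metrics cover only the time where the
    measured rate has reached the set point).
    """
    per_phase: list[float | None] = []
    errs_all = []
    for k in range(len(bounds) - 1):
        t0, t1 = bounds[k], bounds[k + 1]
        sel = df[(df.t_s >= t0 + settling) & (df.t_s < t1) & df.hr_est.notna()]
        if len(sel) == 0:
            per_phase.append(None)
            continue
        errs = np.abs(sel.hr_est.to_numpy() - sel.hr_set.to_numpy())
        per_phase.append(float(errs.mean()))
        errs_all.append(errs)
    overall = float(np.concatenate(errs_all).mean()) if errs_all else None
    return per_phase, overall


def run_pathology_experiment(config: ScenarioConfig, out_dir: str | Path) -> RunReport:
    """Full chain: simulate → render → calibrate → register → extract → classify.

    Persists the vitals and HR streams as CSV under ``out_dir`` and
    returns the phase labels and error summaries.  An empty scenario
    (no phases of either kind) produces an empty report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = default_layout(config.canvas_size)

    vitals_csv = None
    temp_labels: list[PhaseLabel] = []
    calib_model = None
    calib_stats = None

    if config.temperature_phases:
        sensor = config.sensor_model()
        views = default_view_transforms(config.canvas_size, sensor.resolution)
        calib_model, calib_stats, _ = run_calibration_experiment(
            sensor, sensor, seed=_subseed(config.seed, 20)
        )
        pipeline = ThermalPipeline(
            layout,
            calib_model,
            views,
            sensor_resolution=sensor.resolution,
            upscale_factor=config.upscale_factor,
            ransac_threshold=config.ransac_threshold,
            ransac_max_iter=config.ransac_max_iter,
            seed=_subseed(config.seed, 21),
        )
        profile = config.temperature_profile()
        times_t, set_series = simulate_temperature(profile)
        skin = {
            r: skin_temperature(s, config.skin_tau, profile.update_interval)
            for r, s in set_series.items()
        }
        kps = emit_keypoints(layout, config.keypoint_jitter, seed=_subseed(config.seed, 22))
        rois = rois_from_keypoints(kps, layout.canvas_size)

        duration = float(times_t[-1])
        records: list[VitalsRecord] = []
        frame_times = np.arange(0.0, duration + 1e-9, config.thermal_interval)
        for j, tt in enumerate(frame_times):
            i = min(int(np.searchsorted(times_t, tt, side="right")) - 1, times_t.size - 1)
            skin_temps = {r: float(skin[r][i]) for r in skin}
            f1, f2 = render_thermal_pair(
                skin_temps,
                layout,
                sensor,
                view_transforms=views,
                seed=_subseed(config.seed, 1000 + j),
                timestamp=float(tt),
                ambient=config.ambient,
            )
            mos = pipeline.process(f1, f2)
            roi_temps = {name: roi_temperature(mos, roi) for name, roi in rois.items()}
            records.append(
                VitalsRecord(
                    timestamp=float(tt),
                    roi_temps=roi_temps,
                    cptd=compute_cptd(roi_temps),
                    hr=None,
                )
            )

        rows = []
        for r in records:
            row = {"t_s": r.timestamp}
            for name in ("forehead", "chest", "left_hand", "right_hand", "left_foot", "right_foot"):
                row[f"T_{name}"] = r.roi_temps.get(name)
            row["cpTD"] = r.cptd
            row["HR_bpm"] = r.hr
            row["n_valid_intervals"] = r.n_valid_intervals
            rows.append(row)
        vitals_csv = out / "vitals.csv"
        pd.DataFrame(rows).to_csv(vitals_csv, index=False, float_format="%.4f")

        bounds = np.concatenate([[0.0], np.cumsum([p.duration for p in profile.phases])])
        temp_labels = label_phases(records, bounds, settling=config.settling)

    hr_csv = None
    hr_labels: list[PhaseLabel] = []
    per_phase: list[float | None] = []
    overall = None
    if config.hr_phases:
        df, _, hr_bounds = run_hr_pipeline(config, layout)
        hr_csv = out / "hr.csv"
        df.to_csv(hr_csv, index=False, float_format="%.4f")
        hr_records = [
            VitalsRecord(
                timestamp=float(t), roi_temps={}, cptd=None,
                hr=None if np.isnan(hr) else float(hr), n_valid_intervals=int(n),
            )
            for t, hr, n in zip(df.t_s, df.hr_est, df.n_valid_intervals)
        ]
        hr_labels = label_phases(hr_records, hr_bounds, settling=config.settling)
        per_phase, overall = hr_mae(df, hr_bounds, settling=config.settling)

    report = RunReport(
        config=config,
        vitals_csv=vitals_csv,
        hr_csv=hr_csv,
        temperature_phase_labels=temp_labels,
        hr_phase_labels=hr_labels,
        hr_mae_per_phase=per_phase,
        hr_mae_overall=overall,
        calibration_model=calib_model,
        calibration_stats=calib_stats,
    )
    report.phase_table().to_csv(out / "phase_table.csv", index=False)
    return report


# ---------------------------------------------------------------------------
# shipped demonstration scenarios
# ---------------------------------------------------------------------------


def table_style_temperature_scenario(
    phase_duration: float = 600.0, seed: int = 0, **overrides
) -> ScenarioConfig:
    """Seven-phase thermoregulation scenario.

    Phases: moderate hypothermia, normothermia, hyperthermia (fever),
    normothermia, centralization (warm core / cool periphery, cpTD 4 °C),
    severe centralization (cpTD near 6 °C), return to normothermia.  The
    exact set points are this package's choice consistent with those
    conditions.
    """
    phases = [
        {"targets": {"all": 34.0}, "duration": phase_duration},
        {"targets": {"all": 37.0}, "duration": phase_duration},
        {"targets": {"all": 38.5}, "duration": phase_duration},
        {"targets": {"all": 37.0}, "duration": phase_duration},
        {"targets": {"head": 37.0, "torso": 37.0, "limbs": 33.0}, "duration": phase_duration},
        {"targets": {"head": 37.5, "torso": 37.5, "limbs": 31.6}, "duration": phase_duration},
        {"targets": {"all": 37.0}, "duration": phase_duration},
    ]
    kw = dict(
        name="thermoregulation-demo",
        temperature_phases=phases,
        initial_set={"all": 34.0},
        settling=max(120.0, 30.0),
        seed=seed,
    )
    kw.update(overrides)
    return ScenarioConfig(**kw)


def table_style_hr_scenario(
    phase_duration: float = 120.0,
    seed: int = 0,
    include_hrv_phase: bool = True,
    **overrides,
) -> ScenarioConfig:
    """Five-phase cardiac scenario: physiological (140 bpm), severe
    bradycardia (55 bpm), physiological-high (180 bpm), severe
    tachycardia (230 bpm) and physiological with HRV (140 ± 10 bpm
    random walk)."""
    phases = [
        {"hrt": 140.0, "duration": phase_duration, "rmax": 0},
        {"hrt": 55.0, "duration": phase_duration, "rmax": 0},
        {"hrt": 180.0, "duration": phase_duration, "rmax": 0},
        {"hrt": 230.0, "duration": phase_duration, "rmax": 0},
    ]
    if include_hrv_phase:
        phases.append({"hrt": 140.0, "duration": phase_duration, "rmax": 10, "bound": 10.0})
    kw = dict(name="cardiac-demo", hr_phases=phases, seed=seed)
    kw.update(overrides)
    return ScenarioConfig(**kw)
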