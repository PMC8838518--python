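"""Ground-truth vital-sign dynamics of the neonatal phantom.

Two physiological signals are simulated:

* **Surface temperature** — every heatable region follows a set-point
  schedule.  During a heat-up the set temperature is incremented by one
  fixed step width every update interval (default 30 s) so the heating
  rate never exceeds ``max_heat_rate`` (default 1 °C/min, the typical
  thermal dynamics of a neonate); once the target is reached the set
  temperature is held.  A temperature decrease is applied as a single
  jump because passive cooling is slow by itself.

* **Heart rate** — a bounded random walk around a target rate ``hrt``:
  every update interval (default 5 s) a pseudorandom integer step drawn
  uniformly from ``[-rmax, +rmax]`` is added to the set rate, which is
  then clipped to ``[hrt - bound, hrt + bound]``.  This emulates heart
  rate variability (HRV); with ``rmax = 0`` the rate is constant.

The pulsatile photoplethysmography (PPG) waveform driving the phantom's
LEDs is rendered from the heart-rate trace: one pulse per beat, a
raised-cosine systolic peak plus an optional smaller diastolic bump so
that downstream peak detectors must reject minor local maxima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .regions import ALL_REGIONS, RegionId

__all__ = [
    "TemperaturePhase",
    "TemperatureProfile",
    "HRProfile",
    "HRTrace",
    "PPGWaveform",
    "plan_temperature_steps",
    "simulate_temperature",
    "skin_temperature",
    "simulate_hr",
    "generate_ppg",
]


# ---------------------------------------------------------------------------
# profile types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TemperaturePhase:
    """One phase of a temperature schedule.

    Parameters
    ----------
    targets
        Target temperature per region (°C).  Regions absent from the map
        hold their current set temperature.
    duration
        Phase length in seconds (> 0).
    """

    targets: dict[RegionId, float]
    duration: float

    def __post_init__(self) -> None:
        if not (self.duration > 0):
            raise ValueError(f"phase duration must be > 0, got {self.duration}")
        for region, target in self.targets.items():
            if not math.isfinite(target):
                raise ValueError(f"non-finite target for {region}: {target}")


@dataclass(frozen=True)
class TemperatureProfile:
    """Ordered temperature phases plus initial set temperatures."""

    phases: tuple[TemperaturePhase, ...]
    initial_set: dict[RegionId, float]
    max_heat_rate: float = 1.0  # °C/min
    update_interval: float = 30.0  # s

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", tuple(self.phases))
        if not self.phases:
            raise ValueError("profile needs at least one phase")
        if not (self.max_heat_rate > 0):
            raise ValueError("max_heat_rate must be > 0")
        if not (self.update_interval > 0):
            raise ValueError("update_interval must be > 0")


@dataclass(frozen=True)
class HRProfile:
    """Bounded random-walk parameters for the set heart rate.

    ``hrt`` is the target rate; every ``update_interval`` seconds an
    integer step uniform on ``[-rmax, rmax]`` is added and the result is
    clipped to ``hrt ± bound``.  ``hrv_enabled=False`` forces ``rmax=0``.
    """

    hrt: float
    rmax: int = 10
    bound: float = 10.0
    update_interval: float = 5.0
    hrv_enabled: bool = True

    def __post_init__(self) -> None:
        if self.rmax < 0:
            raise ValueError("rmax must be >= 0")
        if self.bound < 0:
            raise ValueError("bound must be >= 0")
        if not (self.update_interval > 0):
            raise ValueError("update_interval must be > 0")
        if not self.hrv_enabled:
            object.__setattr__(self, "rmax", 0)

    @property
    def effective_rmax(self) -> int:
        return self.rmax if self.hrv_enabled else 0


@dataclass(frozen=True)
class HRTrace:
    """Piecewise-constant set heart rate HRS sampled at update instants."""

    times: np.ndarray  # s, strictly increasing
    values: np.ndarray  # bpm

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.shape != values.shape:
            raise ValueError("times and values must have equal shape")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def at(self, t: np.ndarray | float) -> np.ndarray:
        """Set heart rate at time ``t`` (piecewise constant, left limit)."""
        idx = np.clip(np.searchsorted(self.times, t, side="right") - 1, 0, None)
        return self.values[idx]


@dataclass(frozen=True)
class PPGWaveform:
    """Sampled pulsatile intensity in [0, 1] with ground-truth beat onsets."""

    sample_rate: float
    samples: np.ndarray
    beat_times: np.ndarray

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.size and (samples.min() < 0 or samples.max() > 1):
            raise ValueError("PPG samples must lie in [0, 1]")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "beat_times", np.asarray(self.beat_times, dtype=float))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


# ---------------------------------------------------------------------------
# temperature simulation
# ---------------------------------------------------------------------------


def plan_temperature_steps(
    current: float,
    target: float,
    update_interval: float = 30.0,
    max_heat_rate: float = 1.0,
) -> float:
    """Step width (°C per update) from ``current`` toward ``target``.

    Heat-up: equal steps, each at most ``max_heat_rate * update_interval / 60``,
    using the smallest step count that respects the cap, so the target is
    reached exactly.  Cool-down (``target <= current``): a single jump —
    passive cooling needs no software rate limit.
    """
    for name, v in (("current", current), ("target", target)):
        if not math.isfinite(v):
            raise ValueError(f"{name} temperature must be finite, got {v}")
    if not (update_interval > 0):
        raise ValueError("update_interval must be > 0")
    if not (max_heat_rate > 0):
        raise ValueError("max_heat_rate must be > 0")

    delta = target - current
    if delta <= 0:
        return delta
    max_step = max_heat_rate * update_interval / 60.0
    n_steps = math.ceil(delta / max_step)
    return delta / n_steps


def simulate_temperature(
    profile: TemperatureProfile,
) -> tuple[np.ndarray, dict[RegionId, np.ndarray]]:
    """Simulate per-region set-temperature series for a full profile.

    Returns ``(times, series)`` where ``times`` is sampled every
    ``profile.update_interval`` seconds from 0 to the total duration and
    ``series`` maps each region to its set temperature at those times.
    Within each phase the set temperature steps toward the phase target
    (see :func:`plan_temperature_steps`) and holds once reached.
    """
    dt = profile.update_interval
    total = sum(p.duration for p in profile.phases)
    n_samples = int(round(total / dt)) + 1
    times = np.arange(n_samples) * dt

    regions = list(ALL_REGIONS)
    current = {r: float(profile.initial_set.get(r, 0.0)) for r in regions}
    series = {r: np.empty(n_samples) for r in regions}
    for r in regions:
        series[r][0] = current[r]

    i = 1  # next sample index to fill
    elapsed = 0.0
    for phase in profile.phases:
        steps = {}
        targets = {}
        for r in regions:
            tgt = float(phase.targets.get(r, current[r]))
            targets[r] = tgt
            steps[r] = plan_temperature_steps(
                current[r], tgt, dt, profile.max_heat_rate
            )
        elapsed += phase.duration
        phase_end = int(round(elapsed / dt))
        while i <= phase_end and i < n_samples:
            for r in regions:
                tgt = targets[r]
                step = steps[r]
                if current[r] != tgt:
                    if step > 0:
                        current[r] = min(current[r] + step, tgt)
                    else:
                        current[r] = tgt  # single-jump decrease
                series[r][i] = current[r]
            i += 1
        # phase over: any region that has not reached its target keeps
        # stepping into the next phase only if the next phase re-targets it;
        # otherwise it holds (matches the controller, which drops pending
        # steps when a new profile is loaded).
        for r in regions:
            current[r] = series[r][i - 1] if i > 0 else current[r]

    return times, series


def skin_temperature(
    set_series: np.ndarray,
    tau: float,
    update_interval: float = 30.0,
    initial: float | None = None,
) -> np.ndarray:
    """First-order lag of the skin behind the set temperature.

    ``T_skin' = (T_set - T_skin) / tau``; with ``tau = 0`` the skin follows
    the set temperature exactly.  The steady state equals the set value.
    Integrated exactly per sampling interval (exponential update), so a
    step input reproduces the closed-form response at the sample times.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    set_series = np.asarray(set_series, dtype=float)
    if tau == 0:
        return set_series.copy()
    alpha = 1.0 - math.exp(-update_interval / tau)
    out = np.empty_like(set_series)
    out[0] = set_series[0] if initial is None else initial
    for i in range(1, set_series.size):
        # set temperature is piecewise constant over [t_{i-1}, t_i)
        out[i] = out[i - 1] + alpha * (set_series[i - 1] - out[i - 1])
    return out


# ---------------------------------------------------------------------------
# heart rate and PPG
# ---------------------------------------------------------------------------


def simulate_hr(profile: HRProfile, duration: float, seed: int) -> HRTrace:
    """Bounded random walk of the set heart rate.

    Starts at the target ``hrt``; every update adds an integer uniform on
    ``[-rmax, rmax]`` and clips to ``hrt ± bound``.  Identical seeds give
    identical traces.
    """
    if not (duration > 0):
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    dt = profile.update_interval
    n = int(math.floor(duration / dt)) + 1
    times = np.arange(n) * dt
    rmax = profile.effective_rmax
    lo, hi = profile.hrt - profile.bound, profile.hrt + profile.bound
    values = np.empty(n)
    hrs = float(profile.hrt)
    values[0] = hrs
    if rmax == 0:
        values[:] = hrs
    else:
        steps = rng.integers(-rmax, rmax + 1, size=n - 1)
        for i, r in enumerate(steps, start=1):
            hrs = min(max(hrs + float(r), lo), hi)
            values[i] = hrs
    return HRTrace(times=times, values=values)


@dataclass(frozen=True)
class PulseShape:
    """Shape of one PPG pulse, in fractions of the beat period.

    The systolic peak is a raised cosine of amplitude 1; the optional
    diastolic bump is a smaller raised cosine later in the beat, included
    by default so peak detectors must reject minor local maxima.
    """

    systolic_center: float = 0.2
    systolic_width: float = 0.2  # half-width
    secondary_amplitude: float = 0.3
    secondary_center: float = 0.65
    secondary_width: float = 0.15


def _raised_cosine(phase: np.ndarray, center: float, half_width: float) -> np.ndarray:
    x = (phase - center) / half_width
    return np.where(np.abs(x) <= 1.0, 0.5 * (1.0 + np.cos(np.pi * x)), 0.0)


def generate_ppg(
    trace: HRTrace,
    duration: float,
    sample_rate: float = 30.0,
    pulse_shape: PulseShape | None = None,
) -> PPGWaveform:
    """Render the pulsatile PPG waveform for a heart-rate trace.

    One pulse per beat; onsets are spaced ``60 / HRS(t)`` seconds apart
    where ``HRS`` is the piecewise-constant set rate.  The sample rate
    must be at least twice the maximum instantaneous beat frequency.
    """
    if pulse_shape is None:
        pulse_shape = PulseShape()
    max_hz = float(np.max(trace.values)) / 60.0
    if sample_rate < 2.0 * max_hz:
        raise ValueError(
            f"sample_rate {sample_rate} Hz < 2x max beat frequency {max_hz:.3f} Hz"
        )

    # beat bookkeeping: accumulate onsets from the piecewise-constant rate
    onsets = []
    t = 0.0
    while t < duration:
        onsets.append(t)
        hrs = float(trace.at(t))
        t += 60.0 / hrs
    beat_times = np.array(onsets)
    periods = 60.0 / trace.at(beat_times)

    n = int(round(duration * sample_rate))
    times = np.arange(n) / sample_rate
    beat_idx = np.clip(np.searchsorted(beat_times, times, side="right") - 1, 0, None)
    phase = (times - beat_times[beat_idx]) / periods[beat_idx]

    samples = _raised_cosine(phase, pulse_shape.systolic_center, pulse_shape.systolic_width)
    if pulse_shape.secondary_amplitude > 0:
        samples = samples + pulse_shape.secondary_amplitude * _raised_cosine(
            phase, pulse_shape.secondary_center, pulse_shape.secondary_width
        )
    samples = np.clip(samples, 0.0, 1.0)
    return PPGWaveform(sample_rate=sample_rate, samples=samples, beat_times=beat_times)
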