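"""Simulate the phantom's ground-truth vital signs.

Builds a two-phase temperature schedule (warm up from moderate
hypothermia to normothermia, then hold) and a heart-rate random walk,
and prints the resulting traces.  The set temperature rises in equal
steps capped at 1 degC/min; the heart rate stays within +/- 10 bpm of
its 140 bpm target.
"""

import numpy as np

from neophantom import (
    HRProfile,
    RegionId,
    TemperaturePhase,
    TemperatureProfile,
    generate_ppg,
    simulate_hr,
    simulate_temperature,
    skin_temperature,
)

profile = TemperatureProfile(
    phases=[
        TemperaturePhase({r: 37.0 for r in RegionId}, duration=300.0),
        TemperaturePhase({r: 37.0 for r in RegionId}, duration=120.0),
    ],
    initial_set={r: 34.0 for r in RegionId},
)
times, series = simulate_temperature(profile)
chest = series[RegionId.TORSO_MID]
print("time [s]:", times.astype(int).tolist())
print("chest set temperature [C]:", np.round(chest, 2).tolist())
print("-> equal 0.5 C steps every 30 s (1 C/min cap), held once 37.0 C is reached")

skin = skin_temperature(chest, tau=60.0, update_interval=30.0)
print("chest skin temperature (60 s first-order lag):", np.round(skin, 2).tolist())

trace = simulate_hr(HRProfile(hrt=140.0, rmax=10, bound=10.0), duration=60.0, seed=1)
print("\nset heart rate every 5 s [bpm]:", trace.values.astype(int).tolist())
print("-> random integer steps in [-10, 10], clipped to 130..150 bpm")

ppg = generate_ppg(trace, duration=60.0, sample_rate=30.0)
print(f"PPG: {len(ppg.beat_times)} beats rendered in 60 s "
      f"(mean rate {60 * len(ppg.beat_times) / 60:.0f} bpm)")
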