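# neophantom

Desk-scale simulation and camera-based detection of neonatal
pathological states.

Preterm infants in a NICU need continuous vital-sign monitoring, but
adhesive sensors damage immature skin. Contact-free alternatives — RGB
cameras for photoplethysmography imaging (PPGI) and infrared
thermography (IRT) for the skin-temperature distribution — need
validation data with known ground truth, which patient recordings
cannot provide. A hardware patient phantom that simulates surface
temperatures and an LED-driven pulse fills that gap. This package
implements both sides of such a validation study in software, for
researchers developing camera-based neonatal monitoring algorithms:

* **Phantom simulator** — 13 individually heatable body regions follow
  set-point schedules whose heating rate is software-limited to
  1 °C/min (cool-downs jump directly); the set heart rate HRS performs
  a bounded random walk around a target HRT (integer steps uniform on
  [−r_max, r_max] every 5 s, clipped to HRT ± 10 bpm), driving a
  pulsatile PPG waveform with one systolic peak per beat plus a smaller
  diastolic bump.
* **Scene renderer** — two overlapping, low-resolution (160×120)
  thermal views distorted by the inverse of the true sensor response,
  an RGB stream whose head-region red channel carries the PPG, and the
  keypoint skeleton that replaces a pose-estimation network.
* **Detection pipeline** — gain-offset calibration `T_s = K1·T_m + K2`
  fitted by least squares against a reference sweep with
  band-restricted (30–40 °C) error statistics; RANSAC homography
  registration and mosaicking of the thermal views into the RGB
  viewpoint (camera 1 wins in the overlap); keypoint-scaled ROIs
  (forehead, chest, hands, feet); the central-peripheral temperature
  difference cpTD = T_chest − mean(T_peripheral); PPGI heart-rate
  extraction (prominence-selected peaks, inter-beat intervals filtered
  to 36–300 bpm, HR = 60 / mean interval over a 10 s window).
* **Pathology classification** — WHO thermal staging (severe
  hypothermia < 32 °C through severe hyperthermia ≥ 40 °C),
  centralization at |cpTD| > 2 °C, and neonatal heart-rate bands
  (bradycardia < 100, severe < 80; tachycardia > 200, severe
  > 220 bpm), plus majority-vote phase labelling for full scenarios.

## Worked example

`examples/03_registration_mosaic.py` renders a centralization scene
(chest and head 37.0 °C, limbs 33.0 °C) with two gain/offset-distorted
thermal cameras and runs the full thermal pipeline:

```
raw camera-1 readings span 27.57..31.42 C (gain/offset-distorted)
mosaic: 99.6% of canvas covered
  chest       37.00 C
  forehead    37.00 C
  left_hand   33.00 C
  right_hand  33.00 C
  left_foot   33.00 C
  right_foot  33.00 C
cpTD = 4.00 C -> centralization flag: True
```

The raw sensor reads ~27–31 °C for a 33–37 °C scene; after calibration,
registration and mosaicking, every ROI recovers its true temperature
and the chest-minus-periphery difference of 4 °C raises the
centralization flag (an unspecific early sepsis sign when above 2 °C).

`examples/04_ppgi_heart_rate.py` does the same for the cardiac side —
a 60 s rendered video at a set rate of 140 bpm yields

```
140 systolic peaks detected (140 beats simulated; diastolic bumps rejected)
windowed estimates over the last 30 s: median 139.86 bpm, rounded 140 bpm
```

The remaining examples cover ground-truth simulation
(`01_simulate_vitals.py`), calibration fitting and validation
(`02_thermal_calibration.py`) and the complete seven-phase
thermoregulation / five-phase cardiac scenario runs
(`05_full_scenario.py`). A thin CLI (`neophantom simulate | render |
calibrate | register | extract | classify | run-scenario`) wraps the
same functions for shell use.

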