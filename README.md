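# pillowflux

Humidity-flux analysis of sensor-pillow time series: detection of nocturnal
posture changes (tossing and turning) and sleep-posture classification.

## The problem

A linear array of seven combined temperature/humidity sensors (DHT22-class,
±2 %RH) embedded across a pillow sees local relative humidity rise toward a
saturation plateau under the sleeper's head and dry back to baseline when a
posture change releases the contact region. Humidity reacts far faster than
temperature, so posture transitions between *right*, *supine* and *left*
can be recovered from humidity alone. `pillowflux` is for researchers and
engineers building such non-invasive sleep monitors: it provides the full
analysis chain plus a synthetic-session generator with exact ground truth,
so every stage is testable without overnight recordings.

## Method

1. **Humidity flux.** Per-sensor change is collapsed into one non-negative
   statistic. With window mean μᵢ and population standard deviation
   σᵢ = √(1/Nᵢ Σⱼ (xⱼ − μᵢ)²) per subinterval, the std-sum flux is
   S^σ = Σₖ σₖ over the k selected sensors (1-min trailing windows, ≥6
   samples at the 10 s period). A squared-first-difference variant
   Σₖ (hₖ(t) − hₖ(t−1))² is also provided; squaring prevents the opposite-
   signed end-sensor responses of a left↔right turn from cancelling.
2. **Change-point detection.** The min-max normalized flux is piecewise-
   level, so transitions are found by penalized segmentation
   F(t) = min_s {F(s) + C(y_{s+1..t}) + β} with L2 cost, solved exactly by
   PELT; the penalty β is grid-searched (0.05–0.5, step 0.01) to maximize
   F1 against ground truth. Binary Segmentation and BOCPD are included as
   baselines. Detections are scored by one-to-one matching within ±10 s.
3. **Sensor selection.** All C(7,k) subsets for k = 3..6 are rerun through
   the same pipeline and compared with the 7-sensor reference segmentation.
4. **Image classification.** 10-minute windows are rendered as humidity-
   curve images and classified by a compact CNN — conv(32, 3×3) → maxpool →
   conv(64, 3×3) → maxpool → flatten → dense(128) → softmax(3) — trained
   with SGD and inverse-frequency class weights
   w_c = N/(n_classes · N_c) against the supine-dominated label mix.
   Consecutive predicted labels also yield a binary change/no-change
   detector.

## Worked example

```python
import numpy as np
from pillowflux import (SensorArrayConfig, random_schedule, simulate_session,
                        windowed_std_flux, PenaltyGridSearch,
                        evaluate_changepoints)

config = SensorArrayConfig()                      # 7 sensors, 10 s, 0.5 %RH noise
schedule = random_schedule(duration_s=4 * 3600, seed=np.random.default_rng(5))
session = simulate_session(config, schedule, seed=42)

flux = windowed_std_flux(session)                 # 1-min std-sum flux, normalized
search = PenaltyGridSearch().fit(flux.values, schedule.transition_times)
report = evaluate_changepoints(search.change_times_,
                               schedule.transition_times, tolerance_s=10.0)
print(f"penalty={search.best_penalty_:.2f} "
      f"P={report.precision:.2f} R={report.recall:.2f} F1={report.f1:.2f}")
```

prints

```
penalty=0.50 P=1.00 R=1.00 F1=1.00
```

the grid-searched penalty and the tolerance-matched precision, recall and
F1 of the detected posture changes against the simulated ground truth —
on this clean 16-transition night every transition is recovered exactly.

The same pipeline is available from the shell:

```sh
pillowflux simulate --seed 42 --out night.csv --truth-out night.json
pillowflux detect night.csv --truth night.json --out changes.json
pillowflux select-sensors night.csv --truth night.json --out subsets.csv
```

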