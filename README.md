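# majic

**Joint angles from body-worn IMUs, via relative-orientation error-state
Kalman filtering with observability-gated magnetometer use.**

Estimating 3D joint angles from inertial measurement units usually means
estimating each segment's orientation against *global* references —
accelerometer ≈ gravity, magnetometer ≈ magnetic north — and dividing.
Both assumptions break during real movement: limbs accelerate, and indoor
magnetic fields are distorted near floors and electronics. Magnetometer-free
*relative* methods fix the first problem by matching the acceleration both
segments share at the joint center, but without any heading reference they
drift about the acceleration axis whenever motion is gentle.

This package implements a relative error-state Kalman filter that projects
each sensor's readings to a **virtual sensor at the joint center**
(`a_hat = a + alpha x r + omega x (omega x r)`, `b_hat = b`) and fuses the
pair through the implicit measurement `R_WJ y_J - R_WK y_K ~ 0`. A scalar
observability

    o = || a_hat x (d a_hat/dt + omega x a_hat) ||   [m^2/s^5]

measures whether acceleration alone pins down the relative orientation; the
adaptive filter (`majic`) pulls the *joint-center* magnetic field into the
update only when the per-joint observability (minimum over the two
segments) drops below a threshold (default 150 m^2/s^5). Because the field
is compared across one joint rather than against a global north, spatial
distortion hurts far less than in global filters. Three baselines are
included: a per-segment global EKF, the magnetometer-free relative filter
(`magoff`), and the always-on variant (`magon`).

Also included: a synthetic articulated-chain IMU simulator with exact
(symbolically differentiated) ground truth, a uniform-plus-dipole magnetic
field model, scenario presets mirroring gait observability regimes, and
angle-axis RMSE / per-axis Pearson evaluation metrics. Intended users:
biomechanists and movement scientists prototyping IMU fusion pipelines, and
anyone needing a fully testable desk-scale sandbox for relative-orientation
filtering.

## Worked example

```python
from majic import RelativeOrientationKF
from majic.synthetic import scenario_library

# gait-like motion with a magnetic dipole near the distal segment
sim = scenario_library()["distorted_floor"].simulate(duration=20.0)

model = RelativeOrientationKF(
    sim.streams["thigh_imu"], sim.streams["shank_imu"],
    sim.mounts["thigh_imu"]["knee"], sim.mounts["shank_imu"]["knee"],
    method="majic",            # adaptive magnetometer gating
)
results = model.fit()
print(results.summary())
```

```
Relative Orientation Kalman Filter Results
==============================================
joint:                 knee
segments:              thigh -> shank
method:                majic
threshold [m^2/s^5]:   150
samples:               2001
duration [s]:          20.00
magnetometer usage:    11.0% of updates
median o_joint:        345.3 m^2/s^5
final sigma [deg]:     1.458
==============================================
```

The knee is highly observable during gait (median o = 345 m^2/s^5, well
above the 150 gate), so the adaptive filter consulted the distorted
magnetometer in only 11% of updates — the quiet moments of the cycle —
keeping drift bounded without inheriting the distortion. `results` also
carries the estimated quaternion series (`results.orientations`), the
per-step observability trace, a per-step orientation uncertainty
(`results.orientation_std_deg`), `results.to_frame()` for analysis, and
`results.plot()`. Accuracy against ground truth:
`results.rmse_vs(reference)` (total 3D angle-axis RMSE, degrees).

## Command line

```bash
majic simulate --scenario rich_gait --seed 7 --out data/
majic filter   --method majic --config data/run_knee.yaml --out out/
majic evaluate --est out/ --ref data/ --out metrics.csv
majic demo     --scenario distorted_floor --out demo/   # all four methods + metrics
```

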