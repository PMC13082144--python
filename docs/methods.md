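# Methods

## Problem and model

Joint angles from body-worn IMUs are traditionally obtained by estimating
each segment's *global* orientation against world references — the
accelerometer is assumed to measure gravity, the magnetometer magnetic
north — and dividing the two global estimates. Both assumptions fail
routinely: limbs accelerate, and indoor magnetic fields are distorted by
ferrous material and electronics, increasingly so toward the floor.

This package instead estimates the *relative* orientation `R_JK` of two
segments J and K joined by a ball joint directly. Each segment carries an
IMU at a known offset `r` (sensor frame, meters) from the joint center.
Rigid-body dynamics project the measured specific force `a` to a virtual
sensor at the joint center:

    a_hat = a + alpha x r + omega x (omega x r)

with `omega` the measured angular rate and `alpha` its derivative. Because
both segments share the joint center, the two projections are the *same
physical vector* observed in two frames; the same is assumed of the
magnetic field, whose gradient across a joint is taken as negligible
(`b_hat = b`). This yields an implicit measurement per virtual sensor `y`:

    h = R_WJ y_J - R_WK y_K ~ 0

### Error-state filter

The filter state holds nominal orientations `R_WJ`, `R_WK` (the shared
"world" frame is an arbitrary gauge — only the relative product is
meaningful) and a 6x6 covariance `P` of the stacked small-angle errors
`[eta_J; eta_K]`, with true orientation `R = R_nominal exp([eta x])`.

* **Predict** — `R <- R exp(omega dt)` per segment (trapezoidal angular
  rate over the step), error transition `F = blockdiag(exp(omega_J dt)^T,
  exp(omega_K dt)^T)`, process noise `Q = sigma_g^2 dt I_6`.
* **Update** — residual `h` as above, stacked over the active sensor set;
  Jacobian row block `[-R_WJ [y_J x], +R_WK [y_K x]]`. The sign convention
  is pinned by central finite differences of the residual under
  exponential-map perturbations (printed sign conventions in error-state
  filters are a classic transcription hazard; the finite-difference oracle
  is treated as authoritative, and a dedicated test enforces agreement to
  1e-5). With that Jacobian the correction is `eta = -K h`,
  `K = P H^T (H P H^T + R_m)^{-1}` via a linear solve (no explicit
  inverse), Joseph-form covariance update, exact exponential-map injection
  followed by re-orthonormalization, then error reset. The exact injection
  replaces the first-order `I + [eta x]` used in the Jacobian derivation;
  the two agree to `O(||eta||^2)` and the exact map cannot drift off the
  manifold.

A single acceleration pair leaves `H` rank-deficient (a skew matrix has
rank 2): the rotation about the joint-center acceleration axis is
unobservable and drifts under gyro noise/bias. The scalar observability

    o = || a_hat x (d a_hat/dt + omega x a_hat) ||_2     [m^2/s^5]

is zero exactly when the acceleration direction is constant in the segment
frame; the per-joint value is the minimum over the two segments. The norm
is the plain Euclidean 2-norm (not its square) — only then do the units
come out as m^2/s^5, matching the gate threshold's units.

### The four methods

| method  | magnetometer in the update                      |
|---------|--------------------------------------------------|
| ekf     | always, as a *global* north reference (per segment) |
| magoff  | never                                            |
| magon   | always, as a joint-center quantity               |
| majic   | only when `o_joint < threshold` (default 150 m^2/s^5) |

Gating is per timestep with no hysteresis by default (an optional
hysteresis band exists, width 0). The threshold comparison is strict
(`o < threshold`); at the extremes the adaptive method reproduces
`magoff` (threshold 0) and `magon` (threshold infinity) bit-for-bit, which
is tested.

The magnetometer residual uses unit-normalized field vectors, with
`sigma_b` applied to the normalized vector: near distortion sources the
field *magnitude* varies severely, and letting it enter the innovation
would let magnitude error dominate direction information.

The comparison EKF is a standard per-segment error-state filter (3-dim
error) updating against gravity and a fixed world field direction
estimated from the first 2 s of data (configurable, or passed explicitly);
relative output is the quotient of the two global estimates.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| threshold | 150 | m^2/s^5 | observability gate |
| gyro_noise | 0.005 | rad/s/sqrt(Hz) | drives Q; MEMS-grade |
| accel_noise | 0.5 | m/s^2 | per sensor; also absorbs projection/differentiation error |
| mag_noise | 0.05 | — | on the unit-normalized field |
| init_std | 5 deg | — | initial orientation uncertainty |
| smooth_cutoff | 10 | Hz | zero-phase 2nd-order Butterworth before differentiation |

Measurement covariance blocks are `2 sigma^2 I_3` (both segments'
readings contribute independently to each residual block). Angular
acceleration comes from central differences of the low-passed gyro
stream; the observability uses the smoothed `a_hat`. Initial orientations
come from the first accel (tilt) + mag (heading) sample per segment
(ground-truth initialization is available for oracle studies); streams
must share timestamps to within dt/10 — no silent resampling.

## Synthetic data

The simulator prescribes per-axis sinusoidal joint angles (intrinsic
X-Y-Z) on a chain of rigid links plus sinusoidal base motion. Joint-local
rotation, body rate and angular acceleration are differentiated
*symbolically* (sympy, lambdified once per trajectory) and composed with
the exact recursive rigid-body propagation formulas, so ground truth
carries no discretization error — the emitted streams close the loop with
the measurement model to ~1e-14 at the true orientations, and the exact
`alpha` lets oracle tests isolate numerical differentiation error from
filter error. The magnetic field is uniform plus optional point dipoles
(`B = (3 (m.r^)r^ - m)/||r||^3`, the 1/4pi folded into the moment), the
simplest physically shaped distortion. Sensor noise is white Gaussian
per sample plus a constant gyro bias (constant bias is the worst case for
drift; random-walk bias is out of scope). All randomness flows from one
seed; identical seeds give bit-identical streams.

Three frozen presets emulate the observability regimes of gait data on a
pelvis–thigh–shank chain (0.20/0.40/0.40 m, sensors mounted off-axis):

* `quasi_static` — 0.2 Hz, few-degree amplitudes: `o_joint` < 150 for
  >95% of samples (the proximal-joint regime where magnetometer-free
  filters drift);
* `rich_gait` — ~1 Hz cadence, gait-like amplitudes: the distal joint
  exceeds the gate for well over 25% of samples;
* `distorted_floor` — rich gait plus a dipole at (0.85, 0.10, −0.15) m
  with moment (0.0013, 0.0007, 0.002), calibrated once so the distal
  sensor sees |B| ≈ 1.29 ± 0.42 in units of the uniform field — the
  distal-variance regime of real ferrous floors — and then frozen.

What the simulator does **not** model: soft-tissue artifact, sensor
mounting slip, time-varying bias, magnetometer calibration error
(hard/soft iron), sampling jitter, and anatomical joint constraints.
Passing tests therefore demonstrate correctness of the estimation
machinery and the qualitative regime behavior (drift separation,
distortion ordering), not clinical-grade accuracy on human data.

## Numerical choices

* Quaternions are scalar-first with nonnegative scalar; at the angle-axis
  half-turn ambiguity the axis sign makes its first nonzero component
  positive.
* Covariances are symmetrized after every step; positive semidefiniteness
  is enforced (eigenvalue floor −1e−12) and violation raises.
* The innovation solve raises a named error on a singular innovation
  covariance rather than inverting.
* Sensor-to-segment alignment is taken as known (from configuration or
  simulation truth); estimating it from motion is explicitly out of scope.
* Accuracy metrics: per-sample error is the magnitude of the angle-axis
  of `R_ref^T R_est` (total 3D error, no per-plane decomposition); RMSE
  is computed per trial, medians taken across trials/joints. Pearson r is
  computed per angle-axis component. An optional constant pre-alignment
  (Procrustes over the first 2 s) exists but is OFF in every reporting
  path — the conservative choice when no frame alignment is guaranteed.
* Test problem sizes (60 s at 100 Hz for tracking checks, 120 s for drift)
  were chosen as the shortest runs in which the regime behaviors are
  unambiguous.

## Known limitations

* The update stacks accel and mag residuals jointly; sequential updates
  would differ only in linearization points.
* The observability gate uses the instantaneous (smoothed) value; a
  windowed statistic would switch less often near the threshold.
* With exactly one virtual-sensor pair the filter estimates only the
  observable 4 of 6 error dimensions per update; long accel-only runs on
  static data drift by design (that is the phenomenon the adaptive gate
  addresses).
* The EKF baseline's world-field estimate from the first 2 s is only as
  good as that window; on data that starts mid-motion it inherits that
  error, as real global filters do.
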