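# Methods

## Model

The forecaster is a univariate jump network: a single-hidden-layer
feed-forward regressor whose M inputs (the last M minutes of glucose,
mg/dL) feed both L tangent-sigmoid hidden neurons and, through a direct
"jump" connection, the output neuron:

ŷ(t+PH|t) = IOW·I(t)ᵀ + HOW·tanh(IHW·I(t)ᵀ)

The jump term is an unconstrained linear filter over the window — it can
express persistence (weight 1 on the last sample) and linear trend
extrapolation exactly — while the hidden layer adds a bounded nonlinear
correction.  Defaults are M = 10, L = 4, PH = 30 min.  Bias terms exist
in the implementation but default to disabled, matching the bias-free
written form; when enabled they are trained like any other weight.

One model is fitted per patient (precision-medicine setting); no
cross-patient pooling exists anywhere in the pipeline.

## Preprocessing

CGM exports are resampled to a canonical 1-minute grid.  Consecutive
readings at most `max_gap_minutes` (default 10) apart are bridged by
linear interpolation — one missed 5-minute sample is recoverable — and
longer intervals become missing stretches.  A calendar day
(midnight-to-midnight) is retained only if all 1440 of its minutes carry
a reading; maximal runs of consecutive complete days form stand-alone
groups.  Supervised pairs, trailing update windows, and forecast targets
never cross a group boundary.  Duplicate timestamps are averaged;
activity intervals are closed on both ends.

The choice of calendar-day completeness, the 10-minute gap tolerance, and
linear interpolation are package defaults for behaviour the source data
pipeline leaves unspecified; all three are configurable.

## Training

Offline phase (all protocols): pairs whose target falls inside the first
24 h of the first group are split chronologically 80/20; full-batch
gradient descent (lr 0.1) minimises MSE with elementwise gradient
clipping at 0.3, for at most 500 epochs; validation MSE is checked every
4 epochs and training stops after 10 consecutive checks without strict
improvement, returning the best-check weights.  Ties keep the earlier
check; there is no minimum-delta.  Plain gradient descent (not a
momentum/adaptive method) keeps runs exactly reproducible from the seed;
minibatch mode exists behind `batch_size` but the default is full batch —
a first day yields only ~1401 pairs.

**Standardization.**  Training operates on z-scored windows and targets
(one shared mean/sd fitted on the offline training split); predictions
are mapped back to mg/dL.  On raw mg/dL inputs the squared-error Hessian
has curvature of order (mean glucose)²·M ≈ 3·10⁵, so at learning rate 0.1
any first-order method immediately saturates the 0.3 gradient clip and
settles into a fixed-step limit cycle far from the optimum (we measured
validation RMSE frozen at its epoch-4 value through epoch 500, and final
accuracy worse than the persistence baseline, whereas the exact
least-squares solution is clearly better).  Standardization restores the
conditioning under which the stated learning rates are meaningful and
leaves the network equation itself untouched.  It can be disabled with
`ProtocolConfig(standardize=False)`.

Online protocols warm-start from the offline weights.  Every
`update_cadence` = 5 test timestamps, the network takes
`online_epochs_per_update` = 1 full-batch clipped gradient pass
(lr 0.01) over the pairs whose input window *and* target both lie within
the trailing 24 h of CGM ending at the current instant — exactly 1401
pairs once the window is full, and never a sample from the future.  After
a sensor gap, forecasting resumes as soon as an M-history exists inside
the new group, but updates wait until a full trailing day has
accumulated there.  Weights persist across groups.  There is no online
validation or early stopping.  The number of passes per update is not
pinned down by the protocol description; one pass bounds the per-update
cost and is exposed as a config field.

The penalty-weighted protocol replaces the online MSE by
mean(w(t)·e(t)²) with w the piecewise penalty of the error magnitude
(0 / 1 / 2 / 0.5·|e| across the 5, 10, 20 mg/dL breakpoints; boundaries
take the lower branch).  The weight is treated as a constant during
differentiation (a stop-gradient), making the loss a per-sample weighting
rather than a discontinuous objective; weights are always computed on
mg/dL-scale errors, independent of the training standardization.  The
penalty applies to |e| by default: the literal signed rule would leave
large negative errors unpenalised, contradicting its stated purpose, but
it remains available via `use_magnitude=False`.

## Evaluation

The training day is excluded from all test metrics in every protocol.
Per patient, RMSE is reported pooled over every test forecast ("total
days") and pooled over forecasts whose *target* timestamp lies inside an
activity interval ("PA") — pooling, not averaging of per-day RMSEs, which
would differ.  Cohort rows are unweighted means across patients, overall
and within the aerobic/anaerobic strata.  Values are displayed rounded
half-up to one decimal.  A persistence baseline ŷ(t+PH) = y(t), the
standard skill floor for CGM forecasting, runs on identical test
timestamps.

## Synthetic data

The simulator is phenomenological and additive — baseline 120 mg/dL, a
±15 mg/dL circadian sinusoid, bi-exponential meal excursions (3/day,
amplitude 60 ± 15 mg/dL, rise/decay taus 20/60 min, ±30 min timing
jitter), exercise effects (aerobic: linear fall at 8 mg/dL per 10 min
with an equal-length linear recovery; anaerobic: rise to +30 mg/dL by
mid-bout, decay within 120 min), optional pre-exercise snack bumps,
stationary AR(1) sensor noise (φ = 0.8, sd 3 mg/dL), hard clipping to the
40–400 mg/dL sensor range, and scheduled dropout intervals.  Component
random streams are split from one seed in a fixed order so that enabling
one component never perturbs another.  Default schedules give a
multi-day patient 2–8 exercise bouts, the range seen in small sports
cohorts, and keep well over 60 % of samples inside the 70–180 mg/dL
euglycaemic band.

What it does *not* emulate: insulin kinetics, carbohydrate counting,
glucose–insulin feedback, sensor calibration drift, or any real patient's
statistics.  Tests passing on these traces demonstrate that the pipeline
is correct and that the forecaster extracts the structure the simulator
contains (smoothness, excursions, activity-coupled trends); they do not
certify clinical accuracy on real CGM.

## Numerical choices and test scale

- Weight initialisation: Glorot-uniform per weight set, biases zero,
  seeded; training, protocols, and the simulator are deterministic given
  (seed, data, config).
- Gradient clipping is elementwise by value (±0.3), applied in both the
  offline and online phases.
- Degenerate inputs raise typed errors: too-short groups, empty splits,
  non-finite losses (divergence reports the epoch), mismatched shapes.
- End-to-end checks run on a 10-day simulated patient at noise sd
  1 mg/dL ("low noise") over 5 seeds: each protocol must beat persistence
  in at least 3.  At this size a full three-protocol comparison takes a
  few seconds on one CPU; problem sizes in the tests were chosen to keep
  the whole suite fast while leaving every protocol code path exercised.

## Known limitations

- The optimizer, batch regime, initialisation, and presence of biases are
  not pinned down by the protocol description; the defaults above are the
  package's choices and all are exposed in configuration.
- The chronological 20 % validation tail covers late-evening data only,
  so early stopping judges the model on a narrow slice of the day.
- Online updates at a fixed 5-timestamp cadence with one pass cannot
  fully converge to each sliding window's optimum; that is intentional
  (bounded latency), but it means `online_epochs_per_update` trades
  accuracy against cost.
- Cohort averages are unweighted across patients regardless of how many
  days each contributes.
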