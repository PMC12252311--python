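"""Run the preprocessing pipeline on one session.

Kalman-filters the accelerometer axes, downsamples to 1 Hz, joins with
heart rate, cuts 10-s windows labelled with breath-gas VO2, and Z-scores.
"""

import oxyflux as ox
from oxyflux.preprocess import KalmanParams, windows_from_session, zscore_fit

profile = ox.sample_profile(1, "male", "S01")
session = ox.simulate_session(profile, rng_seed=3)

params = KalmanParams()
print(f"Kalman steady-state gain for Q={params.Q}, R={params.R}: "
      f"{params.steady_state_gain():.4f}")
print("≈0.27 means each filtered estimate trusts the new accelerometer "
      "sample about 27% once the filter settles.")

aligned = ox.align_streams(session)
print(f"aligned series: {len(aligned)} seconds x "
      f"{len(aligned.columns) - 1} dynamic features")

ws = windows_from_session(session)
print(f"windows: {len(ws)} of shape {ws.dynamic.shape[1:]} "
      f"(10 seconds x 5 features), {ws.dropped_windows} dropped")
print(f"labels span {ws.labels.min():.2f}–{ws.labels.max():.2f} L/min")

# the scaler needs between-subject variation in the static features,
# so fit it on a small cohort rather than the single session above
from oxyflux.preprocess import windows_from_cohort

cohort_ws = windows_from_cohort(ox.generate_cohort(3, rng_seed=5))
scaler = zscore_fit(cohort_ws)
print("per-feature scaler means:",
      [f"{name}={mu:.2f}" for name, mu in
       zip(cohort_ws.dynamic_names, scaler.dynamic_mean)])
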