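"""Stratify prediction error by ACSM exercise-intensity zone.

Prediction error typically grows in the high-intensity zone, where
physiology is most non-linear and the fewest windows are observed; the
per-zone signed error exposes systematic over/under-estimation.
Reuses a quick training run, so allow a minute or two.
"""

import oxyflux as ox
from oxyflux import models as md
from oxyflux import preprocess as pp
from oxyflux.evaluate import ZONES, assign_zones, zone_report

sessions = ox.generate_cohort(12, rng_seed=3)
ws = pp.windows_from_cohort(sessions)
subs = ws.subjects
tr, va, te = (ws.for_subjects(s)
              for s in (subs[5:], subs[2:5], subs[:2]))
scaler = pp.zscore_fit(tr)
trained = md.train(
    md.ModelConfig(variant="clsa", max_epochs=60, early_stop_patience=12),
    pp.zscore_apply(scaler, tr), pp.zscore_apply(scaler, va))
tes = pp.zscore_apply(scaler, te)
pred = md.predict(trained, tes)

zones = assign_zones(tes.labels, mode="absolute")
rep = zone_report(tes.labels, pred, zones)
print("zone cutoffs (absolute):", rep.cutoffs, "L/min")
for z in ZONES:
    m, n = rep.metrics[z], rep.counts[z]
    if m is None:
        print(f"  {z:>8}: no windows")
    else:
        print(f"  {z:>8}: n={n:3d}  RMSE {m.rmse:.3f}  "
              f"signed error {rep.signed_error[z]:+.3f} L/min")
print("A positive signed error means the model overestimates that zone; "
      "high-intensity windows are usually fewest and worst-predicted.")
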