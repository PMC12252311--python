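"""Apply the three attention blocks to a small feature map.

Temporal attention (TAM) weights time steps; spatial attention (SAM)
weights feature dimensions; STAM cascades both.  All weights are sigmoid
outputs, so they lie strictly in (0, 1) and only rescale the map.
"""

import numpy as np

from oxyflux import SEParams, sam_apply, stam_apply, tam_apply

rng = np.random.default_rng(0)
F = rng.normal(size=(10, 5))  # 10 time steps x 5 features

se = SEParams(W1=rng.normal(size=(5, 10)), W2=rng.normal(size=(10, 5)), r=2)
_, temporal = tam_apply(F, se)
print("temporal weights (one per time step):",
      np.round(temporal.values, 3))

kernel = rng.normal(size=(2, 3))
_, spatial = sam_apply(F, kernel, bias=0.1)
print("spatial weights (one per feature):   ",
      np.round(spatial.values, 3))

out, m, s = stam_apply(F, kernel, se, bias=0.1)
print(f"cascade output shape {out.shape} (unchanged); "
      f"max |weight| product {float(np.max(np.outer(s.values, m.values))):.3f}")

zero_out, _, _ = stam_apply(F, np.zeros((2, 3)), SEParams.zeros(10, r=2))
print("zero-parameter cascade scales the map by",
      float(np.round((zero_out / F).mean(), 3)),
      "(two sigmoid-at-zero gates of 0.5 compose to 0.25)")
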