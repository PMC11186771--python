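"""Negative control: without the range limit there is no clock.

Identical design to bulk_clock.py but the noise is never clamped.
Unbounded symmetric noise cancels on average, so validation predictions
carry no age signal (|r| near 0, or a fully shrunk constant model).
"""

import numpy as np
from scipy.stats import pearsonr

import stochclock as sc

ground = sc.make_ground_state(n_features=500, seed=1)
cfg = sc.NoiseConfig(per_step_sd=0.05, mode="unbounded", seed=2)
dataset = sc.generate_dataset(ground, max_age=100, n_sets=6, cfg=cfg)
train, validation = dataset.train_validation_split(3)

model = sc.train_clock(train, seed=0)
pred = model.predict(validation)

if np.ptp(pred) == 0:
    print("elastic net shrank every coefficient to zero: constant "
          "prediction, no age signal")
else:
    r = pearsonr(validation.ages, pred)[0]
    print(f"validation Pearson r : {r:+.3f}  (no usable signal)")
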