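"""The amount of stochastic variation sets the pace of the clock.

A clock trained at one noise level reads data aged with more per-step
noise as older, and data aged with less noise as younger, at the same
true age: the noise level is the rate of the aging process the clock
measures.
"""

import numpy as np

import stochclock as sc

ground = sc.make_ground_state(n_features=2000, seed=31)
train_cfg = sc.NoiseConfig(per_step_sd=0.2, seed=32)
dataset = sc.generate_dataset(ground, max_age=100, n_sets=3, cfg=train_cfg)
model = sc.train_clock(dataset, seed=0)

rng = np.random.default_rng(33)
print("true age 10, mean predicted age by test-data noise level:")
for sd in (0.05, 0.1, 0.2, 0.4):
    cfg = sc.NoiseConfig(per_step_sd=sd, seed=34)
    preds = [model.predict(
        sc.accumulate_variation(ground, 10, cfg, rng)[None, :])[0]
        for _ in range(30)]
    marker = "(training level)" if sd == 0.2 else ""
    print(f"  sigma {sd:4.2f} : {np.mean(preds):7.1f}  {marker}")
# predictions increase monotonically with the test noise level: doubling
# sigma makes samples hit the trained trajectory's older part earlier.
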