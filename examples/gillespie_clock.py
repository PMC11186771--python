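"""Event-based (Gillespie) methylation simulation.

Instead of discrete maintenance steps, each site switches state through
two reactions (methylation at rate 0.1 per unmethylated cell,
demethylation at rate 0.1 per methylated cell) with exponential waiting
times, observed on an even grid up to tmax = 5.  The continuous-time
drift toward equilibrium carries the same age signal as the discrete
chain.
"""

import stochclock as sc

ground = sc.make_ground_state(n_features=100, seed=1)
cfg = sc.GillespieConfig(switch_rate_on=0.1, switch_rate_off=0.1,
                         tmax=5.0, nrmax=8000, seed=2)
dataset = sc.gillespie_dataset(ground, cfg, n_samples_per_time=6,
                               n_timepoints=21, n_cells=100)
# observation times 0..5 are min-max rescaled to ages 0..100
train, validation = dataset.train_validation_split(3)
model = sc.train_clock(train, seed=0)
report = sc.score_predictions(validation.ages, model.predict(validation))

print(f"validation Pearson r : {report.pearson_r:.3f}")
print(f"validation R^2       : {report.r_squared:.3f}")
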