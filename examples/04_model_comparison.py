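"""Nested-model comparison: is the coupling term necessary?

Trials generated with genuine coupling (k = 16) are fit twice: with the
full delay-coupled model and with the reduced model that only keeps the
intrinsic-period difference (k = 0, which also cancels τ).  The reduced
model can never fit better (it is nested), and fits clearly worse on
average when coupling truly shaped the data.
"""

import numpy as np

from dyadsync import DCSParameters, make_joint_trial, pair_dyad, trim_trial
from dyadsync.fitting import GAConfig, compare_models
from dyadsync.metrics import asynchrony_profile
from dyadsync.synth import GeneratorConfig

cfg = GeneratorConfig(seed=0)
rng = np.random.default_rng(77)
profiles = []
for i in range(8):
    truth = DCSParameters.from_delta(float(rng.normal(0, 5)), 16.0, 16.0, 19.7)
    dyad, _ = make_joint_trial(
        truth, rng, cfg, f"P{i}", "joint_baseline", "delay_first", 1,
        initial_asynchrony_ms=30.0 if i % 2 else -30.0,
    )
    profiles.append(asynchrony_profile(pair_dyad(trim_trial(dyad.trial_a),
                                                 trim_trial(dyad.trial_b))))

df = compare_models(profiles, tau_ms=19.7, seed=3, n_restarts=2,
                    ga=GAConfig(population_size=24, generations=25, patience=8),
                    shared_k=True)
print(df[["trial_ref", "rmse_full", "rmse_reduced", "delta_rmse"]].round(3).to_string(index=False))
print(f"\nmean RMSE — full: {df['rmse_full'].mean():.3f} ms, "
      f"reduced: {df['rmse_reduced'].mean():.3f} ms")
print("delta_rmse ≥ 0 on every trial (nesting); the positive mean gap shows")
print("the coupling term is needed to account for the dyads' asynchronies.")
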