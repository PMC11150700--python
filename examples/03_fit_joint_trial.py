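"""Fit the delay-coupled model to one synthetic joint trial.

A trial is generated with known coupling and period difference; its
repetition-averaged asynchrony profile is then refit with the τ-fixed
two-phase search (genetic algorithm + local refinement).
"""

import numpy as np

from dyadsync import DCSParameters, make_joint_trial, pair_dyad, trim_trial
from dyadsync.fitting import GAConfig, fit_trial_tau_fixed
from dyadsync.metrics import asynchrony_profile
from dyadsync.synth import GeneratorConfig

cfg = GeneratorConfig(seed=4)
truth = DCSParameters.from_delta(8.0, 15.0, 15.0, 19.7)
dyad, _ = make_joint_trial(
    truth, np.random.default_rng(4), cfg, "P01", "joint_baseline",
    "delay_first", 1, initial_asynchrony_ms=-30.0,
)
profile = asynchrony_profile(pair_dyad(trim_trial(dyad.trial_a), trim_trial(dyad.trial_b)))
print("observed profile (ms):", np.round(profile.values_ms, 1))

fit = fit_trial_tau_fixed(
    profile, tau_ms=19.7, n_restarts=3, seed=0,
    ga=GAConfig(population_size=24, generations=25, patience=8),
    shared_k=True,
)
print(f"truth:     k = {truth.k1:5.2f}   Δω = {truth.delta_omega_ms:+6.2f} ms"
      f"   Δω/k = {truth.delta_omega_ms / truth.k1:+.3f}")
print(f"recovered: k = {fit.params.k1:5.2f}   Δω = {fit.params.delta_omega_ms:+6.2f} ms"
      f"   Δω/k = {fit.params.delta_omega_ms / fit.params.k1:+.3f}")
print(f"           (RMSE {fit.rmse:.2f} ms, {fit.n_surviving_restarts}/{fit.n_restarts} restarts kept)")
print("\nA single trial's steady asynchrony level pins the ratio Δω/k tightly,")
print("while k itself is only loosely constrained by the relaxation transient —")
print("study-level conclusions therefore rest on medians over many trials.")
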