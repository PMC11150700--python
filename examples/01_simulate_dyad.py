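"""Forward model: simulate a delay-coupled dyad and read off its asynchronies.

Two phase oscillators (one per partner) tap an 8-tone melody at a 450 ms
period.  With coupling, an initial 30 ms asynchrony relaxes toward the
steady offset set by the partners' intrinsic-period difference; without
coupling the asynchrony drifts by ~Δω per tap.
"""

import numpy as np

from dyadsync import DCSParameters, simulate, simulate_reduced

coupled = DCSParameters.from_delta(
    delta_omega_ms=6.0,   # partner 1 is intrinsically 6 ms/cycle slower
    k1=16.0, k2=16.0,     # symmetric coupling in the empirically fitted range
    tau_ms=19.7,          # each oscillator's memory delay
)

pred = simulate(coupled, n_events=72, initial_asynchrony_ms=30.0)
print("coupled dyad, per-position mean asynchrony (ms, partner1 − partner2):")
print("  ", np.round(pred.predicted_profile, 2))
print("  first taps:", np.round(pred.event_asynchronies_ms[:6], 1),
      "→ last taps:", np.round(pred.event_asynchronies_ms[-3:], 1))
print("  the 30 ms start offset decays to the steady ~level set by Δω/k\n")

drift = simulate_reduced(coupled, n_events=72)
inc = np.diff(drift.event_asynchronies_ms)
print("same periods, coupling removed (reduced model):")
print(f"  asynchrony drifts by {inc.mean():.2f} ms per tap (≈ Δω = 6 ms)")
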