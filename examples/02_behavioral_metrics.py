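"""Behavioral measures: signed asynchronies, variability, solo vs joint.

Generates a small synthetic session (2 pairs) and prints the study-style
summary tables: solo tapping against a recording shows the negative mean
asynchrony (anticipation) and inflated variability under occasionally
delayed feedback; joint tapping with a partner is more synchronous than
solo tapping in absolute asynchrony.
"""

import tempfile
from pathlib import Path

from dyadsync import GeneratorConfig, make_experiment
from dyadsync.pipeline import PipelineConfig, run_behavioral

with tempfile.TemporaryDirectory() as tmp:
    session = Path(tmp) / "session"
    make_experiment(GeneratorConfig(n_pairs=2, seed=7)).write(session)
    tables = run_behavioral(PipelineConfig(input_dir=session, output_dir=Path(tmp) / "out"))

cols = ["task", "order", "mean_signed_asynchrony_ms_mean",
        "sd_signed_asynchrony_ms_mean", "mean_iti_ms_mean"]
print("solo intervention cells (mean over participants):")
print(tables["solo_conditions"][cols].round(1).to_string(index=False))
print("\nnegative means = anticipation of the recording (~ −39 ms);")
print("delayed feedback inflates the asynchrony SD several-fold.\n")

print("solo vs joint absolute asynchrony (per-pair means):")
print(tables["solo_vs_joint"].round(2).to_string(index=False))
print("\npartners synchronize better with each other than with a recording.")
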