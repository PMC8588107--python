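"""Generate a synthetic facial-sEMG dataset and inspect its structure.

Builds one subject's two-session recording campaign (5 tastes x 6
intensities per session, 12 s six-channel trials at 1 kHz), prints the
trial count, the number of distinct tastant solutions involved, and one
trial's per-channel RMS — which grows with intensity for negative-hedonic
tastes like Salty.
"""

import numpy as np

import tastemg as tm

subject = tm.SubjectProfile("S1")
config = tm.GeneratorConfig(seed=42)
trials = tm.generate_dataset([subject], sessions_per_subject=2, config=config)

print(f"trials generated: {len(trials)} (2 sessions x 5 tastes x 6 intensities)")
print(f"distinct solutions used: {len(tm.distinct_solutions(t.stimulus for t in trials))}")

print("\nchannel-2 (depressor anguli oris) RMS by Salty intensity, session 1:")
for t in trials:
    if t.stimulus.taste_type == "Salty" and t.session == 1:
        rms = np.sqrt(np.mean(t.signal[1] ** 2))
        print(f"  intensity {t.stimulus.intensity_index}: {rms:8.1f} uV "
              f"(scale score {t.scale_score:.1f})")
# The RMS here is dominated by baseline wander and mains; the intensity
# trend becomes clean only after preprocessing (see example 02).
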