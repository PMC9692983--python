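"""Robust respiratory features: peak track, CWT ridge, merge.

Extracts both feature tracks from a noise-free Biot's breathing segment
(15 breaths/min bursts interleaved with apnea), applies the artifact
rules, merges the tracks and prints the per-segment medians that feed the
classifier.
"""

import numpy as np

from breathsense import (
    PatternSpec,
    RespiratorySignal,
    artifact_correct,
    cwt_ridge_features,
    fuse_features,
    peak_features,
    smooth,
    synth_segment,
)

fs = 10.0
spec = PatternSpec("biot", 15, 1, 80, "biot_intermittent", (12, 25))
sig = RespiratorySignal(samples=synth_segment(spec, fs), fs=fs)

sm = smooth(sig)
Fp = artifact_correct(peak_features(sm))
Fs = artifact_correct(cwt_ridge_features(sm))
merged = fuse_features(Fp, Fs)

v = merged.valid
print(f"Biot's segment ({spec.rr} breaths/min bursts, effort {spec.re} n.u.):")
print(f"  peak track valid:     {Fp.valid.mean():6.1%}")
print(f"  spectral track valid: {Fs.valid.mean():6.1%}")
print(f"  merged valid:         {v.mean():6.1%}")
print(f"  merged rate median:   {np.median(merged.rr[v]):6.2f} breaths/min")
print(f"  merged amp median:    {np.median(merged.amp[v]):6.2f} n.u.")
print(f"  rate variance median: {np.median(merged.rr_var[v]):6.2f} (breaths/min)^2")

eup = RespiratorySignal(samples=synth_segment(PatternSpec("eupnea", 12, 1, 80, rr_range=(12, 18)), fs), fs=fs)
sm_e = smooth(eup)
merged_e = fuse_features(artifact_correct(peak_features(sm_e)), artifact_correct(cwt_ridge_features(sm_e)))
ve = merged_e.valid
print(f"\neupnea comparison: rate variance median {np.median(merged_e.rr_var[ve]):.4f} (breaths/min)^2")
print("\nThe intermittent pattern's large moving rate variance (vs ~0 for")
print("eupnea) is exactly the feature that separates complex patterns from")
print("constant ones in the classifier.")
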