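"""Simulate imperfect subjects breathing along the reference protocol.

Each synthetic subject is a lagged, rescaled, jittered and noisy rendition
of the reference.  The example recovers every subject's response lag by
cross-correlation and shows the eupnea-based amplitude normalization at
work.
"""

import numpy as np

from breathsense import default_protocol, normalize_to_eupnea, simulate_cohort, synth_protocol
from breathsense.dataset import eupnea_fft_amplitude

ref = synth_protocol(default_protocol())
subjects, configs = simulate_cohort(ref, n_subjects=5, seed=7)

print(f"{'subject':>7} {'true lag [s]':>12} {'xcorr lag [s]':>13} "
      f"{'raw eupnea amp':>15} {'normalized amp':>15}")
for i, (s, cfg) in enumerate(zip(subjects, configs)):
    a = s.samples - s.samples.mean()
    b = ref.samples - ref.samples.mean()
    from scipy.signal import correlate

    lag = (np.argmax(correlate(a, b, "full")) - (len(b) - 1)) / s.fs
    eup = next(seg for seg in s.annotation if seg.label == "eupnea")
    raw = eupnea_fft_amplitude(s.samples[s.segment_slice(eup)])
    norm = normalize_to_eupnea(s, eupnea_span=(eup.start, eup.end))
    after = eupnea_fft_amplitude(norm.samples[norm.segment_slice(eup)])
    print(f"{i:>7} {cfg.lag:>12.2f} {lag:>13.2f} {raw:>15.3f} {after:>15.3f}")

print("\nThe cross-correlation lag matches each subject's configured lag and")
print("normalization maps every subject's eupnea amplitude to 1 n.u., which")
print("makes amplitudes comparable across subjects and modalities.")
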