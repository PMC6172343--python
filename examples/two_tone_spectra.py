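"""Spectral estimation on a gappy two-tone signal.

Builds the 4 Hz + 8 Hz probe signal (amplitude ratio 0.75), deletes 50% of
its samples at random, and compares how well the least-squares Lomb-Scargle
periodogram and the FFT/Welch baselines keep the two tones visible.  The
peak-to-background ratio (PBR) is mean power at the tone frequencies over
the median off-peak power: larger means the tones stand out more clearly.
"""

import numpy as np

from lspdbn import (IncompleteSegment, RemovalSpec, fft_periodogram,
                    lsp_spectrum, normalize_power_by_retention,
                    peak_background_ratio, remove_points, simulate_two_tone,
                    welch_periodogram)

signal = simulate_two_tone(sampling_rate=100.0, duration=10.0, amp_ratio=0.75)
segment = IncompleteSegment(values=signal.values[None, :],
                            timestamps=signal.timestamps,
                            sampling_rate=signal.sampling_rate,
                            original_length=len(signal.values),
                            label=0, source_trial=0, segment_index=0)
gappy = remove_points(segment, RemovalSpec(form="point", proportion=0.5, seed=7))
print(f"retained {gappy.n_retained} of {segment.n_retained} samples "
      f"({gappy.retained_fraction:.0%})\n")

grid = np.arange(1.0, 20.05, 0.1)
for name, estimate in [("lsp", lsp_spectrum(gappy, grid)),
                       ("fft", fft_periodogram(gappy)),
                       ("welch", welch_periodogram(gappy))]:
    estimate = normalize_power_by_retention(estimate)
    keep = estimate.freqs <= 20
    from dataclasses import replace
    estimate = replace(estimate, freqs=estimate.freqs[keep],
                       power=estimate.power[:, keep])
    pbr, detected = peak_background_ratio(estimate, (4.0, 8.0))
    print(f"{name:>5}: peak-to-background ratio {pbr:10.1f}   "
          f"tones detected: {detected}")

print("\nThe LSP fits sinusoids at the true timestamps, so removing half the")
print("samples barely affects it; FFT/Welch see a compressed, distorted")
print("series and their tone peaks sink toward the background.")
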