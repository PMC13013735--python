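"""From speed traces to wave phases and the Kuramoto order parameter.

Plants three oscillators with phase offsets {0, 0, pi} and a 1.5 s wave
period, builds their speed-peak times directly, interpolates phases, and
quantifies synchrony — including the Monte-Carlo chance level.
"""

import numpy as np

from clawtrack import chance_level_R, compute_sync, interpolate_phase, kuramoto_R

period = 1.5
times = np.arange(0, 20, 1 / 30)
offsets = [0.0, 0.0, np.pi]

series = []
for i, off in enumerate(offsets):
    first = (off / (2 * np.pi)) * period
    peaks = np.arange(first, 20.0, period)
    series.append(interpolate_phase(peaks, times, track_id=i))

summary = compute_sync(series, chance_reps=100_000, seed=0)
full = summary.n_active_t == 3
print(f"planted offsets {np.round(offsets, 3)} -> R = |e^i0 + e^i0 + e^ipi| / 3")
print(f"R while all 3 are waving    : {np.nanmean(summary.R_t[full]):.4f} (exact: {1/3:.4f})")
print(
    f"mean R over active instants : {summary.mean_R:.4f} "
    "(higher: at the clip edges only the in-phase pair is active, where R = 1)"
)
print(f"chance level, n=3 oscillators: {summary.chance_R:.4f}")
print(f"chance level, n=2 (closed form 2/pi = {2/np.pi:.4f}): {chance_level_R(2, 100_000, 0):.4f}")
print(f"single-instant check, phases {{0, 0, pi}}: R = {kuramoto_R(np.array([0, 0, np.pi])):.4f}")
# Two crabs waving in phase with a third in antiphase give R = 1/3, well
# above the ~0.44 a trio of independent random phases would average - sample
# size matters when reading R.
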