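"""From speed traces to wave events, phases, and group synchrony.

Each tracked crab's per-frame claw speed is a noisy periodic signal: one
burst per claw wave. The analysis chain is

1. smooth the speed trace (centered moving average),
2. detect the peaks — the moments of highest claw speed, one per wave,
3. treat each crab as an oscillator with phase zero at every peak and
   linearly interpolated phase in between, defined only while the crab is
   actively waving (between its first and last peak),
4. quantify instantaneous group synchrony with the Kuramoto order
   parameter R(t) over all crabs with a defined phase, and compare its mean
   against the chance level for the same number of independent oscillators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "PhaseSeries",
    "SyncSummary",
    "smooth_series",
    "detect_peaks",
    "refine_peak_times",
    "interpolate_phase",
    "kuramoto_R",
    "chance_level_R",
    "compute_sync",
    "extract_phases",
]


@dataclass
class PhaseSeries:
    """Interpolated wave phase of one ID over a common time grid.

    ``phase`` is in ``[0, 2*pi)`` where ``active`` is True and NaN
    elsewhere; phase is zero exactly at each speed peak and increases
    linearly to ``2*pi`` over each cycle. Outside ``[first peak, last
    peak]`` the crab is not considered to be waving and has no phase.
    """

    id: int
    times: np.ndarray
    phase: np.ndarray
    active: np.ndarray
    peak_times: np.ndarray


@dataclass
class SyncSummary:
    """Kuramoto order parameter over time plus scalar summaries.

    ``R_t`` is NaN wherever fewer than two IDs have a defined phase.
    ``mean_R`` averages R over the defined instants; ``chance_R`` is the
    Monte-Carlo expectation of R for the same typical number of independent
    uniform-phase oscillators.
    """

    times: np.ndarray
    R_t: np.ndarray
    n_active_t: np.ndarray
    mean_R: float
    chance_R: float
    n_ids: int
    n_waves: int


def smooth_series(speeds: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edges shrink the window to the samples present.

    ``window`` must be odd so the average is centered. ``window=1`` is the
    identity. Output length equals input length.
    """
    speeds = np.asarray(speeds, dtype=np.float64)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if window > len(speeds):
        raise ValueError(f"window {window} exceeds series length {len(speeds)}")
    if window == 1:
        return speeds.copy()
    kernel = np.ones(window)
    sums = np.convolve(speeds, kernel, mode="same")
    counts = np.convolve(np.ones_like(speeds), kernel, mode="same")
    return sums / counts


def detect_peaks(
    smoothed: np.ndarray, min_prominence: float, min_separation: int
) -> np.ndarray:
    """Find wave peaks: local maxima with enough prominence and spacing.

    Candidates closer than ``min_separation`` frames are resolved in favor
    of the higher peak. Returns frame indices (possibly empty); a monotone
    trace has no local maximum and yields none.
    """
    if min_separation < 1:
        raise ValueError(f"min_separation must be >= 1, got {min_separation}")
    peaks, _ = find_peaks(
        np.asarray(smoothed, dtype=np.float64),
        prominence=min_prominence,
        distance=min_separation,
    )
    return peaks


def refine_peak_times(smoothed: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Sub-frame peak localization by center of mass of each wave burst.

    Cell-averaged cluster speed flattens the top of each wave burst, so the
    frame of the literal maximum can wander several frames along a plateau.
    The center of mass of the burst region (samples above the half-height of
    a window around each detected peak) localizes the wave far more stably.
    The window spans about a third of the typical peak spacing and never
    crosses the midpoint to a neighboring peak. Returns float frame
    positions, one per input peak.
    """
    smoothed = np.asarray(smoothed, dtype=np.float64)
    peaks = np.asarray(peaks, dtype=np.int64)
    if len(peaks) == 0:
        return peaks.astype(np.float64)
    spacing = float(np.median(np.diff(peaks))) if len(peaks) >= 2 else 27.0
    hw = max(3, int(round(spacing / 3.0)))
    refined = np.empty(len(peaks), dtype=np.float64)
    for i, p in enumerate(peaks):
        lo, hi = p - hw, p + hw + 1
        if i > 0:
            lo = max(lo, (peaks[i - 1] + p) // 2 + 1)
        if i < len(peaks) - 1:
            hi = min(hi, (p + peaks[i + 1]) // 2 + 1)
        lo, hi = max(0, lo), min(len(smoothed), hi)
        seg = smoothed[lo:hi]
        weights = np.clip(seg - (seg.max() + seg.min()) / 2.0, 0.0, None)
        refined[i] = (np.arange(lo, hi) * weights).sum() / weights.sum()
    return refined


def interpolate_phase(
    peak_times: np.ndarray, query_times: np.ndarray, track_id: int = -1
) -> PhaseSeries:
    """Piecewise-linear phase between successive peaks.

    Within cycle ``[t_k, t_{k+1})``: ``phase(t) = 2*pi*(t - t_k)/(t_{k+1} - t_k)``,
    wrapped to ``[0, 2*pi)`` so every peak instant maps to exactly 0. Phase
    is undefined (NaN, ``active=False``) before the first and after the last
    peak. Fewer than two peaks means no cycle ever completes: the whole
    series is undefined, with a warning.
    """
    peak_times = np.asarray(peak_times, dtype=np.float64)
    query_times = np.asarray(query_times, dtype=np.float64)
    if len(peak_times) >= 2 and not np.all(np.diff(peak_times) > 0):
        raise ValueError("peak_times must be strictly increasing")
    phase = np.full(len(query_times), np.nan)
    if len(peak_times) < 2:
        warnings.warn(
            f"id {track_id}: {len(peak_times)} peak(s) — no full wave, phase undefined",
            stacklevel=2,
        )
        return PhaseSeries(
            id=track_id,
            times=query_times,
            phase=phase,
            active=np.zeros(len(query_times), dtype=bool),
            peak_times=peak_times,
        )
    active = (query_times >= peak_times[0]) & (query_times <= peak_times[-1])
    t = query_times[active]
    # cycle index of each query: k such that t_k <= t < t_{k+1}
    k = np.clip(np.searchsorted(peak_times, t, side="right") - 1, 0, len(peak_times) - 2)
    frac = (t - peak_times[k]) / (peak_times[k + 1] - peak_times[k])
    phase[active] = np.mod(2.0 * np.pi * frac, 2.0 * np.pi)
    return PhaseSeries(
        id=track_id, times=query_times, phase=phase, active=active, peak_times=peak_times
    )


def kuramoto_R(phases: np.ndarray) -> float:
    """Magnitude of the mean unit phasor: ``R = |mean(exp(i*theta))|``.

    1 means perfect synchrony, values near 0 incoherence. With fewer than
    two phases synchrony is not meaningful and NaN is returned.
    """
    phases = np.asarray(phases, dtype=np.float64)
    phases = phases[np.isfinite(phases)]
    if len(phases) < 2:
        return float("nan")
    return float(np.abs(np.exp(1j * phases).mean()))


def chance_level_R(n: int, reps: int = 10000, seed: int | np.random.Generator = 0) -> float:
    """Expected R for ``n`` independent oscillators with uniform random phases.

    Monte-Carlo mean over ``reps`` draws; seeded and reproducible. For n=2
    the exact value is 2/pi, and for large n it approaches sqrt(pi)/(2*sqrt(n)).
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=(reps, n))
    return float(np.abs(np.exp(1j * theta).mean(axis=1)).mean())


def extract_phases(tracks, config=None) -> list[PhaseSeries]:
    """Wave phases for every track that completed at least one full cycle.

    Runs the smoothing -> peak detection -> phase interpolation chain on
    each track's speed trace, on the clip's frame-time grid. Tracks with
    fewer than two detected peaks never complete a wave and are omitted.
    """
    from .config import PipelineConfig

    config = config or getattr(tracks, "config", None) or PipelineConfig()
    times = np.arange(tracks.n_frames) / tracks.frame_rate
    min_sep = max(1, int(round(config.min_separation_s * tracks.frame_rate)))
    series = []
    for t in tracks:
        smoothed = smooth_series(t.speeds, config.smooth_window)
        peaks = detect_peaks(smoothed, config.wave_min_prominence, min_sep)
        if len(peaks) < 2:
            continue
        peak_t = refine_peak_times(smoothed, peaks) / tracks.frame_rate
        series.append(interpolate_phase(peak_t, times, track_id=t.id))
    return series


def compute_sync(
    series: list[PhaseSeries],
    chance_reps: int = 10000,
    seed: int = 0,
) -> SyncSummary:
    """Population synchrony over the common time grid of ``series``.

    At each instant, R is computed over the IDs whose phase is defined there
    (crabs not actively waving are excluded, not treated as phase 0); below
    two active IDs R is NaN. ``mean_R`` is the time average over defined
    instants. The chance baseline uses the median active count, rounded, so
    it reflects the typical ensemble size.
    """
    if not series:
        raise ValueError("need at least one PhaseSeries")
    times = series[0].times
    for s in series[1:]:
        if len(s.times) != len(times) or not np.allclose(s.times, times):
            raise ValueError("all PhaseSeries must share one time grid")
    phases = np.vstack([s.phase for s in series])  # (n_ids, n_times)
    finite = np.isfinite(phases)
    n_active = finite.sum(axis=0)
    with np.errstate(invalid="ignore"):
        z = np.where(finite, np.exp(1j * np.where(finite, phases, 0.0)), 0.0)
        R = np.abs(z.sum(axis=0)) / np.maximum(n_active, 1)
    R = np.where(n_active >= 2, R, np.nan)
    defined = np.isfinite(R)
    mean_R = float(np.nanmean(R)) if defined.any() else float("nan")
    if defined.any():
        typical_n = max(2, int(round(float(np.median(n_active[defined])))))
        chance = chance_level_R(typical_n, reps=chance_reps, seed=seed)
    else:
        chance = float("nan")
    n_waves = int(sum(max(0, len(s.peak_times) - 1) for s in series))
    return SyncSummary(
        times=times,
        R_t=R,
        n_active_t=n_active,
        mean_R=mean_R,
        chance_R=chance,
        n_ids=len(series),
        n_waves=n_waves,
    )
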