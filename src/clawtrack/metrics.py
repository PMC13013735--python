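"""Detection-accuracy statistics against human annotation.

Individual-count accuracy compares the number of crabs the algorithm found
(``n_alg``) to a human count of the same video (``n_hum``, taken as ground
truth) through three statistics:

* net error          = n_alg - n_hum                       (signed count)
* relative error     = |n_alg - n_hum| / n_hum * 100       (percent)
* agreement accuracy = 100 - relative error                (percent)

Percentages are kept at full precision internally and displayed rounded to
two significant figures. Wave-level accuracy matches detected wave events to
annotated ones in time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DetectionMetrics",
    "net_error",
    "relative_error",
    "agreement_accuracy",
    "wave_detection_accuracy",
    "display_2sf",
]


def net_error(n_alg: int, n_hum: int) -> int:
    """Signed count difference, algorithm minus human."""
    if n_alg < 0 or n_hum < 0:
        raise ValueError("counts must be non-negative")
    return n_alg - n_hum


def relative_error(n_alg: int, n_hum: int) -> float:
    """Unsigned count disagreement as a percentage of the human count.

    Full precision; use :func:`display_2sf` for the two-significant-figure
    display form. The sign of the disagreement is carried by
    :func:`net_error`.
    """
    if n_alg < 0 or n_hum < 0:
        raise ValueError("counts must be non-negative")
    if n_hum == 0:
        raise ValueError("relative error is undefined for a zero human count")
    return abs(n_alg - n_hum) / n_hum * 100.0


def agreement_accuracy(n_alg: int, n_hum: int) -> float:
    """100 minus the relative error, full precision."""
    return 100.0 - relative_error(n_alg, n_hum)


def display_2sf(value: float) -> float:
    """Round a percentage to two significant figures for display.

    Examples: 5.66 -> 5.7, 14.8 -> 15, 85.2 -> 85, 94.3 -> 94.
    """
    if value == 0:
        return 0.0
    digits = 2 - int(np.floor(np.log10(abs(value)))) - 1
    return float(round(value, digits))


@dataclass
class DetectionMetrics:
    """Count-level detection accuracy for one video."""

    n_alg: int
    n_hum: int

    @property
    def net_error(self) -> int:
        return net_error(self.n_alg, self.n_hum)

    @property
    def relative_error(self) -> float:
        return relative_error(self.n_alg, self.n_hum)

    @property
    def agreement_accuracy(self) -> float:
        return agreement_accuracy(self.n_alg, self.n_hum)

    def as_dict(self, display: bool = True) -> dict:
        rel = self.relative_error
        agr = self.agreement_accuracy
        if display:
            rel, agr = display_2sf(rel), display_2sf(agr)
        return {
            "n_alg": self.n_alg,
            "n_hum": self.n_hum,
            "net_error": self.net_error,
            "relative_error_pct": rel,
            "agreement_accuracy_pct": agr,
        }


def wave_detection_accuracy(
    detected: dict[int, np.ndarray],
    truth: dict[int, np.ndarray],
    tolerance: float = 0.5,
) -> float:
    """Percent of annotated wave events matched by a detection in time.

    Per ID, truth and detected event times are matched one-to-one greedily
    in time order: each truth event claims the earliest unused detection
    within ``tolerance`` seconds. IDs present only in ``detected`` contribute
    nothing (spurious detections are not penalized here; count-level metrics
    cover them). Empty truth -> NaN (undefined).
    """
    if not tolerance > 0:
        raise ValueError(f"tolerance must be positive, got {tolerance}")
    n_truth = 0
    n_matched = 0
    for tid, t_events in truth.items():
        t_events = np.sort(np.asarray(t_events, dtype=np.float64))
        d_events = np.sort(np.asarray(detected.get(tid, []), dtype=np.float64))
        n_truth += len(t_events)
        used = np.zeros(len(d_events), dtype=bool)
        for te in t_events:
            ok = np.nonzero(~used & (np.abs(d_events - te) <= tolerance))[0]
            if len(ok):
                used[ok[0]] = True
                n_matched += 1
    if n_truth == 0:
        return float("nan")
    return n_matched / n_truth * 100.0
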