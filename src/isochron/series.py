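"""Core containers: interval series and accelerometer traces.

An :class:`IntervalSeries` holds the ordered durations (ms) of one set of
repeated isochronous wrist flexion-extensions together with its metadata
(subject, taping case, auditory condition, expected tempo).  An
:class:`AccelTrace` holds a uniformly sampled tri-axial acceleration
recording.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ValidationError

#: The two taping cases: without / with elastic therapeutic tape.
CASES = ("N/KTT", "KTT")

#: Auditory conditions: free (no audio), clicks, click recall, music, music recall.
CONDITIONS = ("Fr", "Cl", "Cl2", "Mu", "Mu2")

#: Conditions for which an expected (stimulus) duration exists.
PACED_CONDITIONS = ("Cl", "Cl2", "Mu", "Mu2")

#: Recognized per-set timing-process labels.
REGIME_LABELS = ("event_based", "emergent", "switching")


@dataclass
class IntervalSeries:
    """Ordered movement durations (ms) for one performance set.

    Parameters
    ----------
    durations_ms
        Strictly positive interval durations, in milliseconds.
    subject, case, condition
        Metadata identifying the performance.  ``case`` is one of
        ``"N/KTT"``/``"KTT"``; ``condition`` one of ``Fr, Cl, Cl2, Mu, Mu2``.
    expected_ms
        Stimulus (reference) duration in ms; ``None`` for the free condition.
    rank
        Tempo-range rank 1-8 once assigned, else ``None``.
    set_index
        Index of the set within the session.
    regime_labels
        Optional per-interval timing-process label (used by the synthetic
        generators, e.g. for switching series).
    """

    durations_ms: np.ndarray
    subject: str = "s0"
    case: str = "N/KTT"
    condition: str = "Fr"
    expected_ms: Optional[float] = None
    rank: Optional[int] = None
    set_index: int = 0
    regime_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.durations_ms = np.asarray(self.durations_ms, dtype=float)
        if self.durations_ms.ndim != 1:
            raise ValidationError("durations_ms must be one-dimensional")
        if self.durations_ms.size and np.any(self.durations_ms <= 0):
            raise ValidationError("interval durations must be positive")
        if self.case not in CASES:
            raise ValidationError(f"unknown case {self.case!r}; expected one of {CASES}")
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if self.condition in PACED_CONDITIONS and self.expected_ms is not None:
            if self.expected_ms <= 0:
                raise ValidationError("expected_ms must be positive")
        if self.regime_labels is not None:
            self.regime_labels = np.asarray(self.regime_labels, dtype=object)
            if self.regime_labels.shape != self.durations_ms.shape:
                raise ValidationError("regime_labels must match durations in length")

    def __len__(self) -> int:
        return self.durations_ms.size

    @property
    def mean_ms(self) -> float:
        return float(np.mean(self.durations_ms))

    def errors_s(self) -> np.ndarray:
        """Per-interval error (observed − expected) in seconds.

        For the free condition there is no expected duration; the observed
        duration itself (in seconds) is the response of interest.
        """
        if self.expected_ms is None:
            return self.durations_ms / 1000.0
        return (self.durations_ms - self.expected_ms) / 1000.0


@dataclass
class AccelTrace:
    """Tri-axial acceleration samples on a uniform time grid.

    ``channels`` is ``(n_samples, 3)``; ``t_s`` the matching time stamps in
    seconds; ``sample_rate_hz`` the (uniform) sampling rate.
    """

    t_s: np.ndarray
    channels: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.channels = np.asarray(self.channels, dtype=float)
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be positive")
        if self.channels.ndim != 2 or self.channels.shape[1] != 3:
            raise ValidationError("channels must have shape (n_samples, 3)")
        if self.t_s.shape[0] != self.channels.shape[0]:
            raise ValidationError("timestamp and sample counts differ")
        if self.t_s.size >= 2:
            dt = np.diff(self.t_s)
            if np.any(dt <= 0):
                raise ValidationError("timestamps must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.sample_rate_hz, rtol=1e-6, atol=1e-9):
                raise ValidationError("timestamps are not uniform at sample_rate_hz")

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0]) if self.t_s.size else 0.0

    def __len__(self) -> int:
        return self.t_s.size
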