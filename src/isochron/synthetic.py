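"""Synthetic data generators for the timing-variability pipeline.

Three layers:

* interval-level timing processes — the two-level timekeeper/motor-delay
  model of event-based timing (lag-one autocorrelation in [-0.5, 0]) and a
  first-order autoregressive surrogate for emergent timing (lag-one
  autocorrelation in [0, 0.5)), plus regime-switching concatenations;
* accelerometer traces whose flexion minima fall at cumulative interval
  boundaries, so interval extraction can be exercised end to end;
* full hierarchical study datasets with subject- and set-level random
  effects, condition/tempo fixed effects, and a taping-specific residual
  variance ratio — the structure the heteroscedastic mixed model estimates.

All generators are deterministic given their seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np

from .errors import ValidationError
from .series import AccelTrace, IntervalSeries
from .tempo import REFERENCE_TEMPI_MS, SPEED_THRESHOLD_MS

logger = logging.getLogger(__name__)

RngLike = Union[int, np.random.Generator]

_MAX_RESAMPLE = 100


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Timing-process parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EventBasedParams:
    """Two-level timekeeper model parameters.

    Produced interval n is ``T_n + M_{n+1} - M_n`` with timekeeper intervals
    ``T`` and motor delays ``M`` independent normals.  The implied lag-one
    autocorrelation is ``-sd_M^2 / (sd_T^2 + 2 sd_M^2)``, always in
    ``[-0.5, 0]``.
    """

    mean_interval_ms: float
    timekeeper_sd_ms: float
    motor_delay_sd_ms: float

    def __post_init__(self) -> None:
        if self.mean_interval_ms <= 0:
            raise ValidationError("mean_interval_ms must be positive")
        if self.timekeeper_sd_ms < 0 or self.motor_delay_sd_ms < 0:
            raise ValidationError("standard deviations must be non-negative")

    @property
    def lag_one_autocorr(self) -> float:
        """Theoretical lag-one autocorrelation of produced intervals."""
        denom = self.timekeeper_sd_ms**2 + 2 * self.motor_delay_sd_ms**2
        if denom == 0:
            return 0.0
        return -self.motor_delay_sd_ms**2 / denom

    @property
    def interval_sd_ms(self) -> float:
        """Marginal SD of produced intervals."""
        return float(np.sqrt(self.timekeeper_sd_ms**2 + 2 * self.motor_delay_sd_ms**2))


@dataclass(frozen=True)
class EmergentParams:
    """AR(1) surrogate for emergent (dynamics-driven) timing.

    The stationary lag-one autocorrelation equals ``ar_coefficient``,
    restricted to [0, 0.5) to match the emergent-timing signature.
    """

    mean_interval_ms: float
    ar_coefficient: float
    innovation_sd_ms: float

    def __post_init__(self) -> None:
        if self.mean_interval_ms <= 0:
            raise ValidationError("mean_interval_ms must be positive")
        if not (0.0 <= self.ar_coefficient < 0.5):
            raise ValidationError("ar_coefficient must lie in [0, 0.5)")
        if self.innovation_sd_ms < 0:
            raise ValidationError("innovation_sd_ms must be non-negative")

    @property
    def interval_sd_ms(self) -> float:
        """Marginal (stationary) SD of produced intervals."""
        return float(self.innovation_sd_ms / np.sqrt(1.0 - self.ar_coefficient**2))


ProcessParams = Union[EventBasedParams, EmergentParams]


def _reject_negative(draw, durations: np.ndarray, label: str) -> np.ndarray:
    """Resample non-positive durations in place; keeps durations physical."""
    total = 0
    for _ in range(_MAX_RESAMPLE):
        bad = durations <= 0
        if not bad.any():
            break
        total += int(bad.sum())
        durations[bad] = draw(int(bad.sum()))
    else:
        raise ValidationError(
            f"{label}: could not produce positive durations; SDs too large "
            "relative to the mean interval"
        )
    if total:
        logger.warning("%s: resampled %d non-positive duration(s)", label, total)
    return durations


def gen_event_based(
    params: EventBasedParams, n: int, seed: RngLike, **meta
) -> IntervalSeries:
    """Generate ``n`` intervals from the two-level timekeeper model.

    Timekeeper intervals and motor delays are drawn independently; produced
    interval ``i`` is ``T_i + M_{i+1} - M_i``.  Rarely-occurring non-positive
    durations are resampled (marginally, breaking their serial dependence)
    and logged.
    """
    if n < 2:
        raise ValidationError("n must be at least 2")
    rng = _as_rng(seed)
    t = rng.normal(params.mean_interval_ms, params.timekeeper_sd_ms, size=n)
    m = rng.normal(0.0, params.motor_delay_sd_ms, size=n + 1)
    durations = t + np.diff(m)

    def _redraw(k: int) -> np.ndarray:
        return rng.normal(params.mean_interval_ms, params.interval_sd_ms, size=k)

    durations = _reject_negative(_redraw, durations, "event_based")
    labels = np.full(n, "event_based", dtype=object)
    return IntervalSeries(durations, regime_labels=labels, **meta)


def gen_emergent(params: EmergentParams, n: int, seed: RngLike, **meta) -> IntervalSeries:
    """Generate ``n`` intervals from the stationary AR(1) period process."""
    if n < 2:
        raise ValidationError("n must be at least 2")
    rng = _as_rng(seed)
    phi = params.ar_coefficient
    innov = rng.normal(0.0, params.innovation_sd_ms, size=n)
    x = np.empty(n)
    # stationary start so the lag-one autocorrelation holds from sample one
    x[0] = rng.normal(0.0, params.interval_sd_ms) if params.innovation_sd_ms else 0.0
    for i in range(1, n):
        x[i] = phi * x[i - 1] + innov[i]
    durations = params.mean_interval_ms + x

    def _redraw(k: int) -> np.ndarray:
        return rng.normal(params.mean_interval_ms, params.interval_sd_ms or 1e-12, size=k)

    durations = _reject_negative(_redraw, durations, "emergent")
    labels = np.full(n, "emergent", dtype=object)
    return IntervalSeries(durations, regime_labels=labels, **meta)


def gen_process(params: ProcessParams, n: int, seed: RngLike, **meta) -> IntervalSeries:
    """Dispatch to the generator matching the parameter type."""
    if isinstance(params, EventBasedParams):
        return gen_event_based(params, n, seed, **meta)
    if isinstance(params, EmergentParams):
        return gen_emergent(params, n, seed, **meta)
    raise ValidationError(f"unknown timing-process parameters: {type(params).__name__}")


def gen_switching(
    segments: Sequence[Tuple[ProcessParams, int]], seed: RngLike, **meta
) -> IntervalSeries:
    """Concatenate segments generated by different timing processes.

    A single random stream is threaded through the segments in order, so a
    one-segment call reproduces the plain generator with the same seed.
    Per-interval regime labels are retained for testing windowed
    classification across regime boundaries.
    """
    if not segments:
        raise ValidationError("at least one segment is required")
    rng = _as_rng(seed)
    parts: List[IntervalSeries] = []
    for params, length in segments:
        parts.append(gen_process(params, length, rng))
    durations = np.concatenate([p.durations_ms for p in parts])
    labels = np.concatenate([p.regime_labels for p in parts])
    if len(segments) > 1:
        labels = labels.copy()
    return IntervalSeries(durations, regime_labels=labels, **meta)


# ---------------------------------------------------------------------------
# Accelerometer trace synthesis
# ---------------------------------------------------------------------------


def gen_accel_trace(
    intervals: IntervalSeries,
    sample_rate_hz: float = 200.0,
    noise_sd: float = 0.0,
    seed: RngLike = 0,
    pad_seconds: float = 5.0,
    signal_channel: int = 2,
    amplitude: float = 1.0,
) -> AccelTrace:
    """Synthesize a tri-axial trace whose flexion minima mark the intervals.

    One channel carries a raised-cosine oscillation with a local minimum
    (maximum wrist flexion) at every cumulative interval boundary; the other
    two channels are pure noise.  ``pad_seconds`` of continued oscillation at
    the first/last interval's period is prepended/appended so transient
    trimming can be exercised; with the default 5 s padding and 5 s trim the
    retained events are exactly the true boundaries.
    """
    if sample_rate_hz <= 0:
        raise ValidationError("sample_rate_hz must be positive")
    if len(intervals) == 0:
        raise ValidationError("interval series is empty")
    if not 0 <= signal_channel <= 2:
        raise ValidationError("signal_channel must be 0, 1, or 2")
    rng = _as_rng(seed)

    d_s = intervals.durations_ms / 1000.0
    boundaries = pad_seconds + np.concatenate([[0.0], np.cumsum(d_s)])
    total = boundaries[-1] + pad_seconds
    # ceil so the grid covers the full padded duration: the last movement
    # boundary must stay inside the retained (trimmed) region
    n = int(np.ceil(total * sample_rate_hz - 1e-9)) + 1
    t = np.arange(n) / sample_rate_hz

    # piecewise-linear phase: integer values at boundaries => cosine minima there
    k = np.searchsorted(boundaries, t, side="right") - 1
    phase = np.empty(n)
    pre = k < 0
    phase[pre] = (t[pre] - boundaries[0]) / d_s[0]
    post = k >= len(d_s)
    phase[post] = len(d_s) + (t[post] - boundaries[-1]) / d_s[-1]
    mid = ~(pre | post)
    km = k[mid]
    phase[mid] = km + (t[mid] - boundaries[km]) / d_s[km]

    channels = rng.normal(0.0, noise_sd, size=(n, 3)) if noise_sd > 0 else np.zeros((n, 3))
    channels[:, signal_channel] += -amplitude * np.cos(2 * np.pi * phase)
    return AccelTrace(t_s=t, channels=channels, sample_rate_hz=sample_rate_hz)


# ---------------------------------------------------------------------------
# Hierarchical study generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyDesign:
    """Design of a simulated two-session (taped / untaped) study.

    Each subject performs, in each taping case, ``sets_per_tempo`` sets at
    every reference tempo.  Per-interval error (s) is

    ``mean_error_slow + tempo_effect * fast + subject effect + set effect +
    residual``,

    with the residual SD multiplied by ``sqrt(ktt_variance_ratio)`` for taped
    observations.  Defaults reproduce the magnitudes estimated for the
    clicks condition: within-individual SD 0.0045 s, within-set SD 0.0049 s,
    untaped residual variance 0.00076729 s^2, variance ratio 0.8635, slow
    mean error -0.0063 s, fast-tempo correction +0.0021 s.

    The within-set residual process defaults to the pure-timekeeper limit of
    the event-based model (serially independent residuals, which is what the
    variance model assumes); ``event_motor_fraction`` > 0 or the per-case
    emergent probabilities introduce serial structure for timing-mode
    analyses.
    """

    n_subjects: int = 25
    conditions: Tuple[str, ...] = ("Cl",)
    reference_tempi_ms: Tuple[float, ...] = REFERENCE_TEMPI_MS
    sets_per_tempo: int = 2
    cases: Tuple[str, ...] = ("N/KTT", "KTT")
    within_individual_sd: float = 0.0045
    within_set_sd: float = 0.0049
    residual_sd_nktt: float = 0.0277
    ktt_variance_ratio: float = 0.8635
    mean_error_slow: float = -0.0063
    tempo_effect: float = 0.0021
    intervals_per_set: int = 80
    speed_threshold_ms: float = SPEED_THRESHOLD_MS
    event_motor_fraction: float = 0.0
    emergent_prob_nktt: float = 0.0
    emergent_prob_ktt: float = 0.0
    emergent_ar: float = 0.4

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be at least 1")
        for sd in (self.within_individual_sd, self.within_set_sd, self.residual_sd_nktt):
            if sd < 0:
                raise ValidationError("standard deviations must be non-negative")
        if self.ktt_variance_ratio <= 0:
            raise ValidationError("ktt_variance_ratio must be positive")
        if self.intervals_per_set < 2:
            raise ValidationError("intervals_per_set must be at least 2")
        if not (0.0 <= self.event_motor_fraction < 0.5):
            raise ValidationError("event_motor_fraction must lie in [0, 0.5)")
        for p in (self.emergent_prob_nktt, self.emergent_prob_ktt):
            if not (0.0 <= p <= 1.0):
                raise ValidationError("emergent probabilities must lie in [0, 1]")
        if not (0.0 <= self.emergent_ar < 0.5):
            raise ValidationError("emergent_ar must lie in [0, 0.5)")

    @property
    def sets_per_case(self) -> int:
        return len(self.conditions) * len(self.reference_tempi_ms) * self.sets_per_tempo


@dataclass
class SimulatedStudy:
    """A generated study: interval series plus full provenance."""

    series: List[IntervalSeries]
    set_labels: Dict[Tuple[str, str, str, float, int], str]
    design: StudyDesign
    seed: int

    def to_frame(self):
        """Long per-interval table (one row per produced interval)."""
        import pandas as pd

        rows = []
        for s in self.series:
            label = self.set_labels[(s.subject, s.case, s.condition, s.expected_ms, s.set_index)]
            for i, d in enumerate(s.durations_ms):
                rows.append(
                    (s.subject, s.case, s.condition, s.expected_ms, s.set_index, i, d, label)
                )
        return pd.DataFrame(
            rows,
            columns=[
                "subject",
                "case",
                "condition",
                "tempo_ms_expected",
                "set_index",
                "interval_index",
                "duration_ms",
                "regime_label",
            ],
        )

    def error_frame(self):
        """Per-interval observations for the variance models.

        ``response_s`` is observed − expected duration (s) for paced
        conditions and the observed duration (s) for the free condition.
        """
        import pandas as pd

        rows = []
        for s in self.series:
            set_id = f"{s.subject}|{s.case}|{s.condition}|{s.expected_ms}|{s.set_index}"
            speed = "fast" if (s.expected_ms or s.mean_ms) < self.design.speed_threshold_ms else "slow"
            for resp in s.errors_s():
                rows.append(
                    (s.subject, set_id, s.case, s.condition, int(s.case == "KTT"), speed, resp)
                )
        return pd.DataFrame(
            rows,
            columns=["subject", "set", "case", "condition", "ktt", "speed", "response_s"],
        )


def gen_study(design: StudyDesign, seed: int) -> SimulatedStudy:
    """Generate a full hierarchical study dataset.

    Per-set random substreams are derived deterministically from the master
    seed, so runs with the same (design, seed) are bit-identical.
    """
    master = np.random.SeedSequence(seed)
    n_sets_total = design.n_subjects * len(design.cases) * design.sets_per_case
    children = master.spawn(1 + n_sets_total)
    rng_subj = np.random.default_rng(children[0])

    subject_effects = rng_subj.normal(0.0, design.within_individual_sd, design.n_subjects)

    series: List[IntervalSeries] = []
    labels: Dict[Tuple[str, str, str, float, int], str] = {}
    child_i = 1
    for si in range(design.n_subjects):
        subject = f"s{si:02d}"
        for case in design.cases:
            is_ktt = case == "KTT"
            p_emergent = design.emergent_prob_ktt if is_ktt else design.emergent_prob_nktt
            resid_sd_s = design.residual_sd_nktt * (
                np.sqrt(design.ktt_variance_ratio) if is_ktt else 1.0
            )
            set_index = 0
            for condition in design.conditions:
                for tempo_ms in design.reference_tempi_ms:
                    fast = tempo_ms < design.speed_threshold_ms
                    mu_err = design.mean_error_slow + design.tempo_effect * fast
                    for _ in range(design.sets_per_tempo):
                        rng = np.random.default_rng(children[child_i])
                        child_i += 1
                        v = rng.normal(0.0, design.within_set_sd)
                        mean_ms = tempo_ms + 1000.0 * (
                            mu_err + subject_effects[si] + v
                        )
                        resid_ms = 1000.0 * resid_sd_s
                        if rng.random() < p_emergent:
                            params: ProcessParams = EmergentParams(
                                mean_interval_ms=mean_ms,
                                ar_coefficient=design.emergent_ar,
                                innovation_sd_ms=resid_ms
                                * np.sqrt(1.0 - design.emergent_ar**2),
                            )
                            label = "emergent"
                        else:
                            f = design.event_motor_fraction
                            params = EventBasedParams(
                                mean_interval_ms=mean_ms,
                                timekeeper_sd_ms=resid_ms * np.sqrt(1.0 - 2.0 * f),
                                motor_delay_sd_ms=resid_ms * np.sqrt(f),
                            )
                            label = "event_based"
                        s = gen_process(
                            params,
                            design.intervals_per_set,
                            rng,
                            subject=subject,
                            case=case,
                            condition=condition,
                            expected_ms=tempo_ms if condition != "Fr" else None,
                            set_index=set_index,
                        )
                        series.append(s)
                        labels[(subject, case, condition, s.expected_ms, set_index)] = label
                        set_index += 1
    return SimulatedStudy(series=series, set_labels=labels, design=design, seed=seed)
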