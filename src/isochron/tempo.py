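"""Tempo units, ranked tempo ranges, and the fast/slow dichotomy.

Performed sets are assigned to one of eight ranked tempo bands, each named
after a musical tempo marking and defined by a reference frequency plus a
[from, to] frequency range.  Durations are the reciprocal scale (ms), so a
band covers ``[to_ms, from_ms]`` — higher frequency means shorter interval.
Bands are disjoint with gaps between them, so assignment can come back
empty.  The fast/slow dichotomy splits at 517.33 ms (the short-duration
edge of the Moderato band): strictly shorter durations are "fast".
"""
from __future__ import annotations

import decimal
from dataclasses import dataclass
from importlib import resources
from typing import List, Optional

from .errors import ValidationError

#: Duration boundary of the fast/slow dichotomy (ms). Fast iff strictly below.
SPEED_THRESHOLD_MS = 517.33


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (half-up), as in printed tempo tables."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(value))).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class TempoRange:
    """One ranked tempo band (Hz and ms equivalences)."""

    musical_name: str
    rank: int
    reference_hz: float
    from_hz: float
    to_hz: float
    reference_ms: float
    from_ms: float
    to_ms: float

    def __post_init__(self) -> None:
        if not (self.from_hz <= self.reference_hz <= self.to_hz):
            raise ValidationError("reference_hz must lie inside [from_hz, to_hz]")
        if not (self.to_ms <= self.reference_ms <= self.from_ms):
            raise ValidationError("reference_ms must lie inside [to_ms, from_ms]")

    def contains_ms(self, duration_ms: float) -> bool:
        """Whether a duration falls in this band (bounds inclusive)."""
        return self.to_ms <= duration_ms <= self.from_ms


def _load_table() -> List[TempoRange]:
    rows = []
    text = resources.files("isochron.data").joinpath("tempo_ranges.csv").read_text()
    lines = text.strip().splitlines()
    header = lines[0].split(",")
    for line in lines[1:]:
        rec = dict(zip(header, line.split(",")))
        rows.append(
            TempoRange(
                musical_name=rec["musical_name"],
                rank=int(rec["rank"]),
                reference_hz=float(rec["reference_hz"]),
                from_hz=float(rec["from_hz"]),
                to_hz=float(rec["to_hz"]),
                reference_ms=float(rec["reference_ms"]),
                from_ms=float(rec["from_ms"]),
                to_ms=float(rec["to_ms"]),
            )
        )
    rows.sort(key=lambda r: r.rank)
    return rows


#: The eight ranked tempo bands, ordered by increasing frequency.
TEMPO_RANGES: List[TempoRange] = _load_table()

#: The eight reference durations (ms), rank order.
REFERENCE_TEMPI_MS = tuple(r.reference_ms for r in TEMPO_RANGES)


def hz_to_ms(frequency_hz: float) -> float:
    """Period in ms for a frequency in Hz, rounded half-up to 2 decimals."""
    if frequency_hz <= 0:
        raise ValidationError("frequency must be positive")
    return round_half_up(1000.0 / frequency_hz)


def ms_to_hz(duration_ms: float, ndigits: int = 3) -> float:
    """Frequency in Hz for a period in ms (inverse of :func:`hz_to_ms`)."""
    if duration_ms <= 0:
        raise ValidationError("duration must be positive")
    return round_half_up(1000.0 / duration_ms, ndigits)


def bpm_to_ms(tempo_bpm: float) -> float:
    """Beat period in ms for a tempo in beats per minute."""
    if tempo_bpm <= 0:
        raise ValidationError("tempo must be positive")
    return round_half_up(60000.0 / tempo_bpm)


def assign_rank(mean_duration_ms: float) -> Optional[int]:
    """Rank (1-8) of the band containing a mean duration, or ``None``.

    Bands are inclusive at both duration bounds; a duration falling in the
    gap between two bands is left unassigned rather than snapped to the
    nearest band.
    """
    if mean_duration_ms <= 0:
        raise ValidationError("duration must be positive")
    for band in TEMPO_RANGES:
        if band.contains_ms(mean_duration_ms):
            return band.rank
    return None


def classify_speed(duration_ms: float, threshold_ms: float = SPEED_THRESHOLD_MS) -> str:
    """Dichotomize a duration: ``"fast"`` iff strictly below the threshold."""
    if duration_ms <= 0:
        raise ValidationError("duration must be positive")
    return "fast" if duration_ms < threshold_ms else "slow"
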