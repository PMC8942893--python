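"""Libet-clock geometry: clock configurations and phase/time conversions.

The Libet clock is an analogue clock face with a rotating marker used to
timestamp subjective events: a participant watches the marker and later
reports the clock position at which a judged event (a key-press or a tone)
occurred.  Converting such a report into a time requires the clock's period
(milliseconds per revolution) and the number of report units around the
face (conventionally 60, like minutes on a wall clock).

Two operations live here:

* :func:`position_to_ms` maps a reported clock position (in clock units)
  to a phase in milliseconds within one revolution.
* :func:`wrap_error` computes the signed judgment error — reported phase
  minus actual event time — on the circle, returning the representative
  in ``(-period/2, +period/2]``.  Negative errors are anticipatory reports.

Cosmetic stimulus attributes (marking scheme, hand length, face diameter)
are carried as metadata only; they never enter any computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ClockConfig", "ClockPhase", "position_to_ms", "wrap_error", "wrap_signed"]

#: Marking schemes seen across Libet-clock studies (descriptive only).
MARKING_SCHEMES = ("none", "30'", "15'", "5'", "5'+1'")


@dataclass(frozen=True)
class ClockConfig:
    """Stimulus parameters of one Libet clock.

    Parameters
    ----------
    period_ms
        Duration of one full revolution in milliseconds.  The classic
        paradigm uses 2560 ms; fast and slow variants use 1280 and
        5120 ms.  Any positive value is accepted.
    n_units
        Number of report positions per revolution (default 60).
    markings, hand_length_mm, diameter_mm
        Cosmetic metadata; not used in computation.
    """

    period_ms: float
    n_units: int = 60
    markings: str = "5'"
    hand_length_mm: float | None = None
    diameter_mm: float | None = None

    def __post_init__(self) -> None:
        if not self.period_ms > 0:
            raise ValueError(f"period_ms must be positive, got {self.period_ms}")
        if self.n_units < 2:
            raise ValueError(f"n_units must be >= 2, got {self.n_units}")

    @property
    def ms_per_unit(self) -> float:
        """Milliseconds spanned by one clock unit (period / n_units)."""
        return self.period_ms / self.n_units


@dataclass(frozen=True)
class ClockPhase:
    """An event time reduced modulo the clock period, in ``[0, period_ms)``."""

    phase_ms: float


def position_to_ms(position_units: float, config: ClockConfig) -> ClockPhase:
    """Convert a reported clock position to a phase in milliseconds.

    Fractional positions are accepted: participants report whole numbers,
    but the pipeline must not force integers (quantization belongs to the
    data generator, not the analysis).

    Raises
    ------
    ValueError
        If ``position_units`` lies outside ``[0, n_units)``.
    """
    if not (0 <= position_units < config.n_units):
        raise ValueError(
            f"reported position {position_units!r} outside [0, {config.n_units})"
        )
    return ClockPhase(position_units * config.period_ms / config.n_units)


def wrap_signed(delta_ms, period_ms):
    """Map a time difference onto the circle's symmetric interval.

    Returns the representative of ``delta_ms`` modulo ``period_ms`` lying in
    ``(-period/2, +period/2]``; the boundary tie at exactly half a period is
    assigned to the positive side.  Accepts scalars or numpy arrays.
    """
    half = period_ms / 2.0
    return half - np.mod(half - np.asarray(delta_ms, dtype=float), period_ms)


def wrap_error(
    reported: ClockPhase | float, actual_event_ms: float, config: ClockConfig
) -> float:
    """Signed circular judgment error: reported phase minus actual time.

    The actual event time (since trial onset) may exceed one revolution;
    only its phase matters.  Output lies in ``(-period/2, +period/2]``;
    negative values mean the event was reported earlier than it occurred.
    """
    if actual_event_ms < 0:
        raise ValueError(f"actual_event_ms must be >= 0, got {actual_event_ms}")
    phase = reported.phase_ms if isinstance(reported, ClockPhase) else float(reported)
    return float(wrap_signed(phase - actual_event_ms, config.period_ms))
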