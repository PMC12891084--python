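"""Cosinor rhythmometry: single-component cosine fits, phase differences,
and phase-response of the ED rhythm under dosing.

A cosinor fit regresses a series on ``cos`` and ``sin`` regressors of a fixed
period (24 h here), which is linear least squares; the fitted peak time is the
acrophase.  All phases are reported as clock hours, matching how dose timing
is specified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .event_metrics import Histogram24

__all__ = ["CosinorFit", "cosinor_fit", "phase_difference", "phase_response"]


@dataclass
class CosinorFit:
    """Fitted rhythm parameters: mean level, amplitude, peak time, fit R^2.

    ``degenerate`` flags constant input, for which the acrophase is
    meaningless and reported as 0.
    """

    mesor: float
    amplitude: float
    acrophase_h: float
    r2: float
    period_h: float = 24.0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0.0 <= self.acrophase_h < self.period_h:
            raise ValueError("acrophase_h must lie in [0, period)")


def cosinor_fit(values, times_h, period_h: float = 24.0) -> CosinorFit:
    """Least-squares fit of ``m + A*cos(2*pi*(t - phi)/period)``.

    ``times_h`` are in hours.  Requires at least 4 samples spanning at least
    one period.  The amplitude is reported non-negative with the acrophase
    ``phi`` adjusted into [0, period).
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(times_h, dtype=float)
    if y.shape != t.shape or y.ndim != 1:
        raise ValueError("values and times must be 1-d and equal length")
    if len(y) < 4:
        raise ValueError("need at least 4 samples")
    if t.max() - t.min() < period_h - 1e-9:
        raise ValueError("samples must span at least one period")

    if np.ptp(y) == 0.0:
        # constant series: amplitude 0, acrophase meaningless
        return CosinorFit(
            mesor=float(y[0]),
            amplitude=0.0,
            acrophase_h=0.0,
            r2=0.0,
            period_h=period_h,
            degenerate=True,
        )

    theta = 2.0 * math.pi * t / period_h
    design = np.column_stack([np.ones_like(t), np.cos(theta), np.sin(theta)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    mesor, bc, bs = coef

    sse = float(np.sum((y - design @ coef) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    amplitude = math.hypot(bc, bs)
    acrophase = (math.atan2(bs, bc) * period_h / (2.0 * math.pi)) % period_h
    if acrophase >= period_h:  # guard the float edge of the modulo
        acrophase -= period_h
    return CosinorFit(
        mesor=float(mesor),
        amplitude=float(amplitude),
        acrophase_h=float(acrophase),
        r2=max(0.0, 1.0 - sse / sst),
        period_h=period_h,
    )


def _wrap_half(delta_h: float, period_h: float = 24.0) -> float:
    """Wrap an hour difference into (-period/2, period/2]."""
    half = period_h / 2.0
    wrapped = (delta_h + half) % period_h - half
    if wrapped == -half:
        wrapped = half
    return wrapped


def phase_difference(fit_a: CosinorFit, fit_b: CosinorFit) -> float:
    """Acrophase difference a - b wrapped to (-12, 12] hours.

    Negative values mean rhythm ``a`` peaks before rhythm ``b``.
    """
    if fit_a.amplitude <= 0 or fit_b.amplitude <= 0:
        raise ValueError("phase difference undefined for zero-amplitude fits")
    if fit_a.period_h != fit_b.period_h:
        raise ValueError("fits must share a period")
    return _wrap_half(fit_a.acrophase_h - fit_b.acrophase_h, fit_a.period_h)


def _day_fit(hist: Histogram24) -> CosinorFit:
    # fit bin centers over one day; duplicate the cycle so the span check
    # (>= one period) is met without altering the least-squares solution
    t = np.concatenate([hist.bin_centers_h, hist.bin_centers_h + 24.0])
    v = np.concatenate([hist.counts, hist.counts])
    return cosinor_fit(v, t)


def phase_response(day_first: Histogram24, day_last: Histogram24) -> float:
    """Acrophase shift (hours) of the ED rhythm between two single days.

    Positive values are delays, negative advances; wrapped to (-12, 12].
    Returns NaN when either day has too few events to carry a rhythm.
    """
    if day_first.counts.sum() == 0 or day_last.counts.sum() == 0:
        return float("nan")
    fit_first = _day_fit(day_first)
    fit_last = _day_fit(day_last)
    if fit_first.degenerate or fit_last.degenerate:
        return float("nan")
    return phase_difference(fit_last, fit_first)
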