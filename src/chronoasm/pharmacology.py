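"""Effect-site pharmacokinetics and dose scheduling for anti-seizure drugs.

A single dose produces a bi-exponential effect-site concentration
``C * (exp(-ke*eta) - exp(-ka*eta))`` normalised so its peak is exactly one;
multiple doses superpose linearly.  The drug acts on the model as a
non-positive excitability perturbation ``lambda_asm = -a * concentration``,
where ``a`` is a drug-specific efficacy scale calibrated elsewhere.  Presets
for levetiracetam (LEV), topiramate (TPM) and lamotrigine (LTG) ship as a
data file; they differ essentially in elimination timescale (half-lives of
roughly 7, 21 and 58 hours).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "DrugParams",
    "DoseSchedule",
    "PKProfile",
    "get_drug",
    "drug_names",
    "normalization_constant",
    "single_dose_profile",
    "asm_perturbation",
    "half_life",
    "time_to_steady_state",
    "daily_schedule",
]

SECONDS_PER_HOUR = 3600.0
SECONDS_PER_DAY = 86400.0

#: Dose contributions below this are dropped from the superposition sum.
CONTRIBUTION_CUTOFF = 1.0e-9


@dataclass(frozen=True)
class DrugParams:
    """One-compartment absorption/elimination rates plus the efficacy scale."""

    name: str
    ka: float  # absorption rate, 1/s
    ke: float  # elimination rate, 1/s
    a: float  # efficacy scale (dimensionless)

    def __post_init__(self) -> None:
        if not (self.ka > self.ke > 0):
            raise ValueError(
                f"require ka > ke > 0, got ka={self.ka}, ke={self.ke}"
            )
        if self.a < 0:
            raise ValueError("efficacy scale a must be >= 0")

    def with_a(self, a: float) -> "DrugParams":
        return replace(self, a=a)


def _load_presets() -> dict:
    raw = resources.files("chronoasm.data").joinpath("drugs.json").read_text()
    table = json.loads(raw)
    return {
        key: DrugParams(
            name=entry["name"],
            ka=entry["ka_per_h"] / SECONDS_PER_HOUR,
            ke=entry["ke_per_h"] / SECONDS_PER_HOUR,
            a=entry["a"],
        )
        for key, entry in table.items()
    }


_PRESETS = _load_presets()


def get_drug(name: str) -> DrugParams:
    """Preset drug parameters by name (LEV, TPM or LTG)."""
    try:
        return _PRESETS[name.upper()]
    except KeyError:
        raise KeyError(
            f"unknown drug {name!r}; available: {sorted(_PRESETS)}"
        ) from None


def drug_names() -> list:
    return sorted(_PRESETS)


def normalization_constant(ka: float, ke: float) -> float:
    """Constant C scaling the bi-exponential profile to a unit peak.

    The profile peaks at ``t* = ln(ka/ke)/(ka - ke)``;
    ``C = 1 / (exp(-ke t*) - exp(-ka t*))``.
    """
    if not (ka > ke > 0):
        raise ValueError("require ka > ke > 0 for an interior maximum")
    t_star = math.log(ka / ke) / (ka - ke)
    return 1.0 / (math.exp(-ke * t_star) - math.exp(-ka * t_star))


@dataclass(frozen=True)
class PKProfile:
    """Closed-form summary of a drug's single-dose profile."""

    normalization: float  # C
    t_peak: float  # hours
    half_life: float  # hours


def pk_profile(drug: DrugParams) -> PKProfile:
    t_star = math.log(drug.ka / drug.ke) / (drug.ka - drug.ke)
    return PKProfile(
        normalization=normalization_constant(drug.ka, drug.ke),
        t_peak=t_star / SECONDS_PER_HOUR,
        half_life=half_life(drug),
    )


def single_dose_profile(eta, drug: DrugParams):
    """Normalised effect-site concentration ``eta`` seconds after a dose.

    Zero for negative ``eta``; rises at rate ``ka``, falls at ``ke``, peak 1.
    Accepts scalars or arrays.
    """
    c = normalization_constant(drug.ka, drug.ke)
    eta_arr = np.asarray(eta, dtype=float)
    out = np.where(
        eta_arr < 0,
        0.0,
        c * (np.exp(-drug.ke * eta_arr) - np.exp(-drug.ka * eta_arr)),
    )
    return float(out) if np.isscalar(eta) else out


def half_life(drug: DrugParams) -> float:
    """Elimination half-life ln(2)/ke, in hours."""
    return math.log(2.0) / drug.ke / SECONDS_PER_HOUR


@dataclass
class DoseSchedule:
    """Daily dosing schedule: once (QD) or twice (BID) per day.

    The primary dose is given at clock time ``primary_phase_h`` each day and
    carries fraction ``f`` of the total daily dose; in BID mode the remaining
    ``1 - f`` follows ``dosing_interval_h`` later (12 h by default).  The
    "dose phase" of an experiment is this clock time read against the 24 h
    cycle whose ED peak sits at hour 12.
    """

    mode: str  # "QD" or "BID"
    primary_phase_h: float  # clock time of the first daily dose, [0, 24)
    f: float = 1.0  # primary dose fraction
    dosing_interval_h: float = 12.0
    start_time: float = 0.0  # first dose time, s from simulation start
    end_time: float = SECONDS_PER_DAY  # last dosing-day boundary, s

    def __post_init__(self) -> None:
        if self.mode not in ("QD", "BID"):
            raise ValueError(f"mode must be 'QD' or 'BID', got {self.mode!r}")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must lie in [0, 1]")
        if self.mode == "QD" and self.f != 1.0:
            raise ValueError("QD schedules require f = 1")
        if not 0.0 <= self.primary_phase_h < 24.0:
            raise ValueError("primary_phase_h must lie in [0, 24)")
        if self.end_time <= self.start_time:
            raise ValueError("end_time must exceed start_time")

    def primary_times(self) -> np.ndarray:
        """Times of the daily primary doses (s)."""
        return np.arange(self.start_time, self.end_time, SECONDS_PER_DAY)

    def dose_events(self) -> Tuple[np.ndarray, np.ndarray]:
        """All impulse times and their dose weights, sorted by time."""
        primaries = self.primary_times()
        if self.mode == "QD":
            return primaries, np.full(len(primaries), self.f)
        secondaries = primaries + self.dosing_interval_h * SECONDS_PER_HOUR
        times = np.concatenate([primaries, secondaries])
        weights = np.concatenate(
            [np.full(len(primaries), self.f), np.full(len(secondaries), 1.0 - self.f)]
        )
        order = np.argsort(times, kind="stable")
        return times[order], weights[order]


def daily_schedule(
    mode: str,
    phase_h: float,
    f: float = 1.0,
    start_day: int = 0,
    n_days: int = 1,
    dosing_interval_h: float = 12.0,
) -> DoseSchedule:
    """Convenience constructor: dose daily at clock time ``phase_h`` for
    ``n_days`` days starting on day ``start_day``."""
    start = start_day * SECONDS_PER_DAY + phase_h * SECONDS_PER_HOUR
    end = (start_day + n_days) * SECONDS_PER_DAY + phase_h * SECONDS_PER_HOUR
    return DoseSchedule(
        mode=mode,
        primary_phase_h=phase_h % 24.0,
        f=f,
        dosing_interval_h=dosing_interval_h,
        start_time=start,
        end_time=end - 1.0,  # n_days primaries exactly
    )


def asm_perturbation(t, schedule: DoseSchedule, drug: DrugParams):
    """Total drug-induced excitability perturbation at time ``t`` (<= 0).

    Direct superposition over all administered doses:
    ``-a * sum_i [f * profile(t - t_i) + (1 - f) * profile(t - t_i - tau)]``.
    Doses whose contribution has decayed below :data:`CONTRIBUTION_CUTOFF`
    are dropped.  Accepts scalars or arrays.
    """
    times, weights = schedule.dose_events()
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    # look-back horizon after which a unit dose has decayed below the cutoff
    c = normalization_constant(drug.ka, drug.ke)
    horizon = math.log(c / CONTRIBUTION_CUTOFF) / drug.ke
    total = np.zeros_like(t_arr)
    for ti, wi in zip(times, weights):
        if wi == 0.0:
            continue
        eta = t_arr - ti
        mask = (eta >= 0) & (eta <= horizon)
        if np.any(mask):
            total[mask] += wi * c * (
                np.exp(-drug.ke * eta[mask]) - np.exp(-drug.ka * eta[mask])
            )
    out = -drug.a * total
    return float(out[0]) if np.isscalar(t) else out


def steady_state_mean_perturbation(drug: DrugParams) -> float:
    """Asymptotic 24 h mean of the perturbation under one total daily dose.

    By AUC linearity this is ``-a * C * (1/ke - 1/ka) / 86400`` regardless of
    how the daily dose is split or timed.
    """
    c = normalization_constant(drug.ka, drug.ke)
    return -drug.a * c * (1.0 / drug.ke - 1.0 / drug.ka) / SECONDS_PER_DAY


def time_to_steady_state(
    drug: DrugParams, tolerance: float = 0.01, max_days: int = 120
) -> int:
    """First day whose 24 h mean perturbation is within ``tolerance`` of the
    asymptotic mean, under one QD unit dose per day.

    Day counting is 1-based: day 1 is the first 24 h after the first dose.
    """
    if not 0.0 < tolerance <= 1.0:
        raise ValueError("tolerance must lie in (0, 1]")
    target = abs(steady_state_mean_perturbation(drug))
    schedule = daily_schedule("QD", 0.0, n_days=max_days + 1)
    grid = np.arange(0.0, SECONDS_PER_DAY, 60.0)
    for day in range(1, max_days + 1):
        t = (day - 1) * SECONDS_PER_DAY + grid
        mean_day = abs(np.mean(asm_perturbation(t, schedule, drug)))
        if abs(mean_day - target) <= tolerance * target:
            return day
    raise RuntimeError(f"steady state not reached within {max_days} days")


def kernel_dose_arrays(
    schedule: Optional[DoseSchedule], drug: Optional[DrugParams]
) -> Tuple[np.ndarray, np.ndarray, float, float, float]:
    """Dose times/weights and rate constants in the form the kernel consumes."""
    if schedule is None:
        return np.empty(0), np.empty(0), 0.0, 1.0, 1.0
    assert drug is not None
    times, weights = schedule.dose_events()
    a_c = drug.a * normalization_constant(drug.ka, drug.ke)
    return times, weights, a_c, drug.ke, drug.ka
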