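"""The in-silico dosing experiments: efficacy calibration, QD dose-phase
sweeps, BID fraction-by-phase sweeps, and chronotype grid fitting.

Every experiment follows the same protocol skeleton: an unmedicated burn-in,
a dosing window long enough for the drug to reach its steady-state daily mean,
and a final measurement window over which the mean hourly ED rate is taken.
Efficacy is the percentage reduction of that rate relative to an independent
unmedicated baseline arm (rates are averaged per arm before the reduction is
formed; per-run reductions against the baseline mean are reported alongside).

Seeding: a root seed deterministically spawns one child seed per
(arm, condition, run) via ``numpy.random.SeedSequence`` spawn keys, so whole
sweeps are reproducible bit for bit and arms are statistically independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chronometrics import phase_response
from .core_dynamics import ModelParams, SimConfig, Trajectory, simulate
from .event_metrics import Histogram24, hourly_histogram, mean_hourly_rate, efficacy
from .pharmacology import DrugParams, daily_schedule

__all__ = [
    "ExperimentProtocol",
    "FULL_PROTOCOL",
    "DESK_PROTOCOL",
    "BaselineArm",
    "SweepResult",
    "CalibrationResult",
    "ChronotypeFit",
    "child_seed",
    "sweep_phases",
    "run_baseline",
    "calibrate_a",
    "qd_phase_sweep",
    "bid_sweep",
    "synthesize_histogram",
    "fit_chronotype",
    "clear_histogram_cache",
]

SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class ExperimentProtocol:
    """Shared experimental skeleton for all dosing experiments."""

    burn_in_days: int = 2  # unmedicated lead-in
    dosing_days: int = 28
    measure_days: int = 7  # final window used for rates
    n_phases: int = 10  # dose phases per sweep
    n_runs: int = 10  # replicates per condition
    dt: float = 0.001
    record_stride: int = 60_000  # 60 s trajectory samples

    def __post_init__(self) -> None:
        if self.measure_days > self.dosing_days:
            raise ValueError("measure_days must not exceed dosing_days")
        if self.n_phases < 1 or self.n_runs < 1:
            raise ValueError("n_phases and n_runs must be >= 1")
        if min(self.burn_in_days, self.dosing_days, self.measure_days) < 0:
            raise ValueError("day counts must be non-negative")

    @property
    def total_days(self) -> int:
        return self.burn_in_days + self.dosing_days

    @property
    def measure_window(self) -> Tuple[float, float]:
        start = (self.total_days - self.measure_days) * SECONDS_PER_DAY
        return (start, self.total_days * SECONDS_PER_DAY)


#: The full experimental protocol (28 dosing days, 10 phases, 10 runs).
FULL_PROTOCOL = ExperimentProtocol()
#: Reduced protocol exercising every code path at desk scale.
DESK_PROTOCOL = ExperimentProtocol(
    burn_in_days=2, dosing_days=4, measure_days=3, n_phases=5, n_runs=3
)


def child_seed(root: int, *keys: int) -> int:
    """Deterministic child seed below 2**31 for a (root, keys...) label."""
    ss = np.random.SeedSequence(entropy=int(root), spawn_key=tuple(int(k) for k in keys))
    return int(ss.generate_state(1)[0] % (2**31))


def sweep_phases(n_phases: int) -> np.ndarray:
    """Evenly spaced dose phases (clock hours) across the 24 h cycle."""
    return np.arange(n_phases) * 24.0 / n_phases


def _run_one(
    params: ModelParams,
    protocol: ExperimentProtocol,
    seed: int,
    schedule=None,
    drug: Optional[DrugParams] = None,
) -> Trajectory:
    config = SimConfig(
        duration=protocol.total_days * SECONDS_PER_DAY,
        seed=seed,
        dt=protocol.dt,
        record_stride=protocol.record_stride,
    )
    return simulate(params, config, schedule=schedule, drug=drug)


# arm indices used in spawn keys
_ARM_BASELINE = 0
_ARM_TREATED = 1
_ARM_FIXTURE = 2


@dataclass
class BaselineArm:
    """Unmedicated replicate runs and their measurement-window rates."""

    rates: np.ndarray  # mean hourly ED rate per run over the measure window
    runs: list  # the trajectories (decimated) with events attached
    protocol: ExperimentProtocol

    @property
    def mean_rate(self) -> float:
        return float(np.mean(self.rates))


def run_baseline(
    params: ModelParams,
    protocol: ExperimentProtocol,
    seed: int,
    n_runs: Optional[int] = None,
) -> BaselineArm:
    """Run the independent unmedicated arm of an experiment."""
    n_runs = protocol.n_runs if n_runs is None else n_runs
    window = protocol.measure_window
    runs = []
    rates = []
    for run in range(n_runs):
        traj = _run_one(params, protocol, child_seed(seed, _ARM_BASELINE, run))
        runs.append(traj)
        rates.append(mean_hourly_rate(traj.events, window))
    arm = BaselineArm(rates=np.array(rates), runs=runs, protocol=protocol)
    if arm.mean_rate == 0:
        raise RuntimeError("degenerate baseline: no ED events in measure window")
    return arm


@dataclass
class SweepResult:
    """Per-run efficacy table plus per-condition aggregates for one sweep."""

    drug: str
    mode: str
    table: pd.DataFrame  # one row per (phase, f, run)
    summary: pd.DataFrame  # one row per (phase, f)
    baseline_rate: float
    baseline_rates: np.ndarray

    @property
    def phase_spread_pct(self) -> float:
        """Max minus min of the per-phase mean reductions (single-f sweeps)."""
        return float(
            self.summary["reduction_pct"].max() - self.summary["reduction_pct"].min()
        )

    def best_phase(self) -> float:
        idx = self.summary["reduction_pct"].idxmax()
        return float(self.summary.loc[idx, "phase_h"])


def _dosing_day_histograms(
    traj: Trajectory, protocol: ExperimentProtocol
) -> Tuple[Histogram24, Histogram24]:
    first_start = protocol.burn_in_days * SECONDS_PER_DAY
    last_start = (protocol.total_days - 1) * SECONDS_PER_DAY
    return (
        hourly_histogram(traj.events, first_start, first_start + SECONDS_PER_DAY),
        hourly_histogram(traj.events, last_start, last_start + SECONDS_PER_DAY),
    )


def _sweep(
    drug: DrugParams,
    mode: str,
    fractions: Sequence[float],
    protocol: ExperimentProtocol,
    params: ModelParams,
    seed: int,
    baseline: Optional[BaselineArm] = None,
    phases: Optional[Sequence[float]] = None,
    progress=None,
) -> SweepResult:
    if baseline is None:
        baseline = run_baseline(params, protocol, seed)
    window = protocol.measure_window
    phases = sweep_phases(protocol.n_phases) if phases is None else np.asarray(phases)
    rows = []
    cond = 0
    for f in fractions:
        for phase in phases:
            if progress is not None:
                progress(f"{drug.name} {mode} f={f:g} phase={phase:g} h")
            schedule = daily_schedule(
                mode, phase, f=f, start_day=protocol.burn_in_days,
                n_days=protocol.dosing_days,
            )
            for run in range(protocol.n_runs):
                traj = _run_one(
                    params,
                    protocol,
                    child_seed(seed, _ARM_TREATED, cond, run),
                    schedule=schedule,
                    drug=drug,
                )
                rate = mean_hourly_rate(traj.events, window)
                h_first, h_last = _dosing_day_histograms(traj, protocol)
                rows.append(
                    {
                        "drug": drug.name,
                        "mode": mode,
                        "phase_h": phase,
                        "f": f,
                        "run": run,
                        "medicated_rate": rate,
                        "reduction_pct": efficacy(rate, baseline.mean_rate),
                        "phase_shift_h": phase_response(h_first, h_last),
                    }
                )
            cond += 1
    table = pd.DataFrame(rows)
    # arm-level efficacy: average rates within the condition, then reduce
    summary = (
        table.groupby(["phase_h", "f"], as_index=False)
        .agg(medicated_rate=("medicated_rate", "mean"),
             phase_shift_h=("phase_shift_h", "mean"))
    )
    summary["reduction_pct"] = [
        efficacy(r, baseline.mean_rate) for r in summary["medicated_rate"]
    ]
    summary["drug"] = drug.name
    summary["mode"] = mode
    return SweepResult(
        drug=drug.name,
        mode=mode,
        table=table,
        summary=summary,
        baseline_rate=baseline.mean_rate,
        baseline_rates=baseline.rates,
    )


def qd_phase_sweep(
    drug: DrugParams,
    protocol: ExperimentProtocol,
    params: ModelParams,
    seed: int,
    baseline: Optional[BaselineArm] = None,
    phases: Optional[Sequence[float]] = None,
    progress=None,
) -> SweepResult:
    """Once-daily dosing at evenly spaced dose phases.

    Returns per-phase efficacy and the cosinor phase shift of the ED rhythm
    between the first and last dosing day.  ``phases`` (clock hours) replaces
    the default even spacing when given.
    """
    return _sweep(
        drug, "QD", [1.0], protocol, params, seed, baseline, phases, progress
    )


def bid_sweep(
    drug: DrugParams,
    fractions: Sequence[float],
    protocol: ExperimentProtocol,
    params: ModelParams,
    seed: int,
    baseline: Optional[BaselineArm] = None,
    phases: Optional[Sequence[float]] = None,
    progress=None,
) -> SweepResult:
    """Twice-daily dosing over a (fraction x phase) grid.

    ``fractions`` are primary-dose fractions in [0.5, 0.9]; the secondary dose
    follows 12 h later with the remainder of the constant total daily dose.
    """
    for f in fractions:
        if not 0.5 <= f <= 0.9:
            raise ValueError("primary dose fractions must lie in [0.5, 0.9]")
    return _sweep(
        drug, "BID", list(fractions), protocol, params, seed, baseline, phases,
        progress,
    )


def per_fraction_range(result: SweepResult) -> pd.DataFrame:
    """Max-minus-min reduction over phases, per dose fraction."""
    g = result.summary.groupby("f")["reduction_pct"]
    out = (g.max() - g.min()).reset_index()
    return out.rename(columns={"reduction_pct": "range_pct"})


@dataclass
class CalibrationResult:
    """Sweep of the efficacy scale ``a`` against the ~50% reduction target."""

    drug: str
    mode: str
    a_grid: np.ndarray
    reduction_curve: np.ndarray  # mean % reduction per a
    a_star: float
    table: pd.DataFrame


def calibrate_a(
    drug: DrugParams,
    mode: str,
    a_grid: Sequence[float],
    protocol: ExperimentProtocol,
    params: ModelParams,
    seed: int,
    target_pct: float = 50.0,
    progress=None,
) -> CalibrationResult:
    """Calibrate the concentration-to-excitability scale ``a``.

    For each grid value the drug is dosed at ``protocol.n_phases`` evenly
    spaced phases (the phase-averaged "control condition"); the reported
    reduction is against the ``a = 0`` arm, which must be in the grid.
    ``a_star`` is the grid value whose reduction is nearest ``target_pct``.
    """
    a_grid = np.asarray(sorted(a_grid), dtype=float)
    if 0.0 not in a_grid:
        raise ValueError("a_grid must include 0 (the unmedicated arm)")
    baseline = run_baseline(params, protocol, seed)
    rows = []
    curve = []
    for ia, a in enumerate(a_grid):
        if a == 0.0:
            reduction = efficacy(baseline.mean_rate, baseline.mean_rate)
            curve.append(reduction)
            rows.append({"a": a, "reduction_pct": reduction})
            continue
        if progress is not None:
            progress(f"calibrating {drug.name} {mode}: a={a:g}")
        res = _sweep(
            drug.with_a(a), mode, [1.0] if mode == "QD" else [0.5],
            protocol, params, child_seed(seed, 3, ia), baseline,
        )
        mean_med = float(res.table["medicated_rate"].mean())
        reduction = efficacy(mean_med, baseline.mean_rate)
        curve.append(reduction)
        rows.append({"a": a, "reduction_pct": reduction})
    curve = np.asarray(curve)
    a_star = float(a_grid[np.argmin(np.abs(curve - target_pct))])
    return CalibrationResult(
        drug=drug.name,
        mode=mode,
        a_grid=a_grid,
        reduction_curve=curve,
        a_star=a_star,
        table=pd.DataFrame(rows),
    )


_HISTOGRAM_CACHE: Dict[tuple, Histogram24] = {}


def clear_histogram_cache() -> None:
    _HISTOGRAM_CACHE.clear()


def synthesize_histogram(
    rho: float,
    lambda0: float,
    seed: int,
    days: int = 2,
    params: Optional[ModelParams] = None,
    dt: float = 0.001,
) -> Histogram24:
    """Day-averaged hourly ED histogram of an unmedicated run.

    This is the fixture generator for chronotype fitting: it emulates a 24 h
    ED-rate histogram with a single circadian peak whose amplitude grows with
    ``rho`` and whose overall rate grows with ``lambda0``.  Results are cached
    by (rho, lambda0, seed, days).
    """
    key = (float(rho), float(lambda0), int(seed), int(days), float(dt))
    if key in _HISTOGRAM_CACHE:
        return _HISTOGRAM_CACHE[key]
    base = ModelParams() if params is None else params
    p = base.with_overrides(rho=rho, lambda0=lambda0)
    config = SimConfig(
        duration=days * SECONDS_PER_DAY,
        seed=child_seed(seed, _ARM_FIXTURE),
        dt=dt,
        record_stride=60_000,
    )
    traj = simulate(p, config)
    hist = hourly_histogram(traj.events, 0.0, days * SECONDS_PER_DAY)
    _HISTOGRAM_CACHE[key] = hist
    return hist


@dataclass
class ChronotypeFit:
    """Best (rho, lambda0) grid point for a target 24 h ED histogram."""

    rho_star: float
    lambda0_star: float
    r2: float
    residuals: np.ndarray  # per-hour, best simulation minus target
    sse_grid: np.ndarray  # (len(rho_grid), len(lambda0_grid))
    rho_grid: np.ndarray
    lambda0_grid: np.ndarray


def fit_chronotype(
    target: Histogram24,
    rho_grid: Sequence[float],
    lambda0_grid: Sequence[float],
    seed: int,
    days: int = 2,
    params: Optional[ModelParams] = None,
) -> ChronotypeFit:
    """Least-squares grid search of (rho, lambda0) against a target histogram.

    Simulates (or reads cached) unmedicated histograms at every grid point and
    selects the minimiser of the per-hour sum of squared differences.  ``r2``
    is 1 - SSE/SST of the best fit against the target.
    """
    rho_grid = np.asarray(list(rho_grid), dtype=float)
    lambda0_grid = np.asarray(list(lambda0_grid), dtype=float)
    if rho_grid.size == 0 or lambda0_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if target.counts.sum() == 0:
        raise ValueError("target histogram contains no events")
    sse = np.empty((len(rho_grid), len(lambda0_grid)))
    best = None
    for i, rho in enumerate(rho_grid):
        for j, lam0 in enumerate(lambda0_grid):
            hist = synthesize_histogram(rho, lam0, seed, days=days, params=params)
            err = hist.counts - target.counts
            sse[i, j] = float(np.dot(err, err))
            if best is None or sse[i, j] < best[0]:
                best = (sse[i, j], i, j, hist)
    _, i_star, j_star, best_hist = best
    sst = float(np.sum((target.counts - target.counts.mean()) ** 2))
    r2 = 1.0 - best[0] / sst if sst > 0 else 0.0
    return ChronotypeFit(
        rho_star=float(rho_grid[i_star]),
        lambda0_star=float(lambda0_grid[j_star]),
        r2=float(r2),
        residuals=best_hist.counts - target.counts,
        sse_grid=sse,
        rho_grid=rho_grid,
        lambda0_grid=lambda0_grid,
    )
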