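"""Energy-trace statistics and CG-vs-atomistic calibration fits.

Consumes MD-style total-energy time series (two-column whitespace text, xvg
dialect) and provides the error heuristics used to attach uncertainties to
per-conformation mean energies: the effective sample count ``N = floor(T /
tau)`` with ``tau`` a hydrogen-bond lifetime, the standard error of the mean
``sigma / sqrt(N)``, a random half-subset consistency check, and ordinary
least-squares calibration of mean atomistic energies against dimensionless
CG energies.  A seeded AR(1) generator stands in for MD output in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal, stats

__all__ = [
    "EnergyTrace",
    "TraceStats",
    "CalibrationPoint",
    "CalibrationFit",
    "HBondBalance",
    "read_energy_trace",
    "write_energy_trace",
    "trace_statistics",
    "effective_sample_count",
    "sem_estimate",
    "running_average",
    "half_split_check",
    "fit_calibration",
    "sidechain_series_fit",
    "combined_reference",
    "hbond_balance",
    "generate_energy_trace",
]


@dataclass
class EnergyTrace:
    """Uniformly sampled energy time series (times in ps, energies kJ/mol).

    ``duration`` is ``n_samples * dt`` -- each sample represents one sampling
    interval, so a 10 ns trace sampled every 0.1 ps has duration 10000 ps.
    """

    times: np.ndarray
    energies: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.energies.shape:
            raise ValueError("times and energies must be equal-length 1-D arrays")
        if len(self.times) < 2:
            raise ValueError("a trace needs at least 2 samples")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ValueError("sample times must be strictly increasing")
        dt = steps[0]
        if np.any(np.abs(steps - dt) > 1e-9 * max(abs(dt), 1.0)):
            raise ValueError("sample times must be uniformly spaced")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt


@dataclass
class TraceStats:
    mean: float
    sigma: float
    correlation_time: float
    n_effective: int
    sem: float


@dataclass
class CalibrationPoint:
    """One conformation: CG energy, mean atomistic energy and its SEM."""

    e_p20: float
    e_aa: float
    sem: float
    n_backbone: int
    n_sidechain: int

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("SEM must be >= 0")


@dataclass
class CalibrationFit:
    slope: float          # kJ/mol per dimensionless CG unit
    intercept: float      # kJ/mol
    residual_std: float
    r_squared: float
    n_points: int


@dataclass
class HBondBalance:
    e_pep_pep: float
    e_wat_wat: float
    e_pep_wat: float
    delta: float


def read_energy_trace(path) -> EnergyTrace:
    """Parse two-column whitespace text; '#' and '@' lines are comments."""
    data = np.loadtxt(path, comments=["#", "@"], ndmin=2)
    if data.shape[0] < 2:
        raise ValueError(f"{path}: need at least 2 data rows")
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time, energy)")
    return EnergyTrace(data[:, 0], data[:, 1])


def write_energy_trace(trace: EnergyTrace, path, comment: str = "") -> None:
    header = "time (ps)  energy (kJ/mol)"
    if comment:
        header = comment + "\n" + header
    np.savetxt(path, np.column_stack([trace.times, trace.energies]),
               fmt="%.10g", header=header)


def effective_sample_count(total_time: float, correlation_time: float) -> int:
    """``N = floor(T / tau)``: independent samples in a correlated trace."""
    if correlation_time <= 0:
        raise ValueError("correlation time must be > 0")
    if total_time < correlation_time:
        raise ValueError("correlation time exceeds the trace duration")
    return int(math.floor(total_time / correlation_time))


def sem_estimate(sigma: float, total_time: float, correlation_time: float) -> float:
    """``sigma / sqrt(N)`` with ``N = floor(T / tau)``."""
    return sigma / math.sqrt(effective_sample_count(total_time, correlation_time))


def trace_statistics(trace: EnergyTrace, correlation_time: float) -> TraceStats:
    """Mean, standard deviation, effective N and SEM of a trace."""
    n_eff = effective_sample_count(trace.duration, correlation_time)
    mean = float(np.mean(trace.energies))
    sigma = float(np.std(trace.energies))
    return TraceStats(mean, sigma, correlation_time, n_eff,
                      sigma / math.sqrt(n_eff))


def running_average(series: Sequence[float], window: int) -> np.ndarray:
    """Centered box average; edges use the truncated window."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("series must be non-empty")
    if window < 1:
        raise ValueError("window must be >= 1 sample")
    if window == 1:
        return series.copy()
    half = (int(window) - 1) // 2
    half_hi = int(window) - 1 - half
    cumsum = np.concatenate([[0.0], np.cumsum(series)])
    n = series.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half_hi, n - 1)
    return (cumsum[hi + 1] - cumsum[lo]) / (hi - lo + 1)


def half_split_check(trace: EnergyTrace,
                     rng: np.random.Generator | int | None = None,
                     ) -> tuple[float, float, float]:
    """(full mean, mean of a random half-subset, their difference)."""
    if trace.n_samples < 4:
        raise ValueError("half-split check needs at least 4 samples")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = trace.n_samples
    subset = rng.choice(n, size=n // 2, replace=False)
    full = float(np.mean(trace.energies))
    half = float(np.mean(trace.energies[subset]))
    return full, half, half - full


def _as_xy(points: Sequence[CalibrationPoint]) -> tuple[np.ndarray, np.ndarray]:
    x = np.array([p.e_p20 for p in points], dtype=float)
    y = np.array([p.e_aa for p in points], dtype=float)
    return x, y


def fit_calibration(points: Sequence[CalibrationPoint]) -> CalibrationFit:
    """Unweighted OLS of mean atomistic energy against CG energy."""
    points = list(points)
    if len(points) < 2:
        raise ValueError("calibration fit needs at least 2 points")
    x, y = _as_xy(points)
    if np.all(x == x[0]):
        raise ValueError("calibration fit needs at least 2 distinct CG energies")
    res = stats.linregress(x, y)
    predicted = res.intercept + res.slope * x
    residuals = y - predicted
    dof = max(len(points) - 2, 1)
    residual_std = float(np.sqrt(np.sum(residuals ** 2) / dof))
    return CalibrationFit(float(res.slope), float(res.intercept),
                          residual_std, float(res.rvalue ** 2), len(points))


def sidechain_series_fit(points: Sequence[CalibrationPoint],
                         ) -> dict[int, CalibrationFit]:
    """One OLS fit per backbone-count group (fixed nb, varying ns)."""
    groups: dict[int, list[CalibrationPoint]] = {}
    for p in points:
        groups.setdefault(p.n_backbone, []).append(p)
    fits: dict[int, CalibrationFit] = {}
    for nb in sorted(groups):
        members = groups[nb]
        if len(members) < 2:
            raise ValueError(
                f"backbone-count group {nb} has {len(members)} point(s); "
                "need at least 2")
        fits[nb] = fit_calibration(members)
    return fits


def combined_reference(e_water: float, e_peptide: float, n_peptides: int) -> float:
    """Reference energy of a solvated multi-peptide box: water + n * peptide."""
    if n_peptides < 0:
        raise ValueError("n_peptides must be >= 0")
    return e_water + n_peptides * e_peptide


def hbond_balance(e_pep_pep: float, e_wat_wat: float,
                  e_pep_wat: float) -> HBondBalance:
    """Hydrogen-bond partner-swap balance: pep-pep + wat-wat - 2 * pep-wat."""
    for v in (e_pep_pep, e_wat_wat, e_pep_wat):
        if not math.isfinite(v):
            raise ValueError("energies must be finite")
    return HBondBalance(e_pep_pep, e_wat_wat, e_pep_wat,
                        e_pep_pep + e_wat_wat - 2.0 * e_pep_wat)


def generate_energy_trace(mean: float, stdev: float, correlation_time: float,
                          dt: float, duration: float, seed: int) -> EnergyTrace:
    """Stationary AR(1) trace with marginal (mean, stdev^2) and lag-1
    autocorrelation ``exp(-dt / correlation_time)``; deterministic per seed."""
    if stdev < 0:
        raise ValueError("stdev must be >= 0")
    if not (0 < dt <= duration):
        raise ValueError("need 0 < dt <= duration")
    if correlation_time <= 0:
        raise ValueError("correlation time must be > 0")
    n = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    phi = math.exp(-dt / correlation_time)
    innovations = rng.normal(0.0, stdev * math.sqrt(1.0 - phi * phi), size=n)
    innovations[0] = stdev * rng.normal()  # stationary start
    deviations = signal.lfilter([1.0], [1.0, -phi], innovations)
    times = np.arange(n) * dt
    return EnergyTrace(times, mean + deviations)
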