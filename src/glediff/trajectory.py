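"""Estimators and diagnostics for 2D trajectories and MSD curves.

Time-averaged MSD and VACF (FFT-based, O(N log N)), local MSD exponent
alpha(t), time-dependent diffusion coefficient D(t), the cumulative
squared-displacement distribution Pi(r^2, Delta) used as a Gaussianity
check, mass-weighted group averages, and residence-time-based selection of
the lipid shell nearest a reference particle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .curves import ObservableCurve
from .errors import ParameterDomainError

__all__ = [
    "Trajectory2D",
    "CumulativeDistribution",
    "time_averaged_msd",
    "vacf_estimate",
    "local_exponent",
    "time_dependent_D",
    "cumulative_displacement_distribution",
    "gaussianity_exponent",
    "mass_weighted_group_curve",
    "select_near",
]


@dataclass
class Trajectory2D:
    """Uniformly sampled 2D center-of-mass trajectory.

    Attributes
    ----------
    times : ndarray, shape (N,)
        Sampling times, ps, uniform step.
    positions : ndarray, shape (N, 2)
        Coordinates, nm.
    mass : float
        Particle mass, g/mol.
    label : str
        Free-text identifier.
    velocities : ndarray or None
        Optional (N, 2) velocities, nm/ps; derived by central differences
        when absent.
    """

    times: np.ndarray
    positions: np.ndarray
    mass: float = 1.0
    label: str = ""
    velocities: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ParameterDomainError("positions must have shape (N, 2)")
        if len(self.times) != len(self.positions) or len(self.times) < 2:
            raise ParameterDomainError("need N >= 2 matching times/positions")
        steps = np.diff(self.times)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=0.0) or steps[0] <= 0:
            raise ParameterDomainError("times must be uniform and increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ParameterDomainError("positions must be finite")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ParameterDomainError("velocities must match positions shape")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)

    def finite_difference_velocities(self) -> np.ndarray:
        """Central-difference velocities (one-sided at the ends), nm/ps."""
        return np.gradient(self.positions, self.dt, axis=0)


def _as_traj_list(traj) -> list[Trajectory2D]:
    if isinstance(traj, Trajectory2D):
        return [traj]
    trajs = list(traj)
    if not trajs:
        raise ParameterDomainError("need at least one trajectory")
    return trajs


def _lag_indices(traj: Trajectory2D, lags) -> np.ndarray:
    dt = traj.dt
    if lags is None:
        n = len(traj)
        idx = np.unique(
            np.round(np.logspace(0, np.log10(n - 1), 120)).astype(int)
        )
        return idx
    lags = np.asarray(lags, dtype=float)
    idx = np.round(lags / dt).astype(int)
    if np.any(np.abs(idx * dt - lags) > 1e-6 * dt + 1e-12):
        raise ParameterDomainError("lags must be multiples of the sampling step")
    if np.any(idx < 1) or np.any(idx >= len(traj)):
        raise ParameterDomainError("lags must lie within the trajectory span")
    return np.unique(idx)


def _msd_fft_1d(x: np.ndarray) -> np.ndarray:
    """Time-averaged MSD of one coordinate for all lags, O(N log N).

    Uses MSD(m) = (S1(m) - 2 S2(m)) / (N - m) with S2 the autocorrelation
    computed by FFT and S1 from cumulative sums of squares.
    """
    n = len(x)
    nfft = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, nfft)
    s2 = np.fft.irfft(fx * np.conj(fx), nfft)[:n]
    x2 = x * x
    # S1(m) = sum_{k=m}^{N-1} x_k^2 + sum_{k=0}^{N-1-m} x_k^2
    css = np.cumsum(x2)
    total = css[-1]
    m = np.arange(n)
    tail = total - np.concatenate(([0.0], css[:-1]))  # sum_{k=m}^{N-1}
    head = css[::-1]  # sum_{k=0}^{N-1-m}
    s1 = tail + head
    return (s1 - 2.0 * s2) / (n - m)


def time_averaged_msd(traj, lags=None) -> ObservableCurve:
    """Time-averaged MSD over sliding origins, ensemble-averaged when a list
    of trajectories is given.

    MSD(Delta) = mean over origins t0 of |X(t0+Delta) - X(t0)|^2; computed by
    the FFT correlation identity in O(N log N).  ``lags`` (ps) must be
    multiples of the sampling step; defaults to a log-spaced subset.
    """
    trajs = _as_traj_list(traj)
    idx = _lag_indices(trajs[0], lags)
    acc = np.zeros(len(idx))
    for tr in trajs:
        if abs(tr.dt - trajs[0].dt) > 1e-9 * trajs[0].dt:
            raise ParameterDomainError("trajectories must share the sampling step")
        msd_full = _msd_fft_1d(tr.positions[:, 0]) + _msd_fft_1d(tr.positions[:, 1])
        acc += msd_full[idx]
    values = np.maximum(acc / len(trajs), 0.0)
    return ObservableCurve(
        idx * trajs[0].dt,
        values,
        "msd",
        meta={"estimator": "time-averaged, overlapping origins", "n_traj": len(trajs)},
    )


def msd_direct(traj: Trajectory2D, lags=None) -> ObservableCurve:
    """O(N^2) double-loop MSD (reference implementation for cross-checks)."""
    idx = _lag_indices(traj, lags)
    pos = traj.positions
    vals = np.empty(len(idx))
    for i, m in enumerate(idx):
        d = pos[m:] - pos[:-m]
        vals[i] = np.mean(np.sum(d * d, axis=1))
    return ObservableCurve(idx * traj.dt, vals, "msd", meta={"estimator": "direct"})


def _acf_fft(v: np.ndarray) -> np.ndarray:
    """Time-averaged autocorrelation sum_axis <v(t0+m) . v(t0)> for all m."""
    n = len(v)
    nfft = 1 << (2 * n - 1).bit_length()
    acf = np.zeros(n)
    for c in range(v.shape[1]):
        f = np.fft.rfft(v[:, c], nfft)
        acf += np.fft.irfft(f * np.conj(f), nfft)[:n]
    return acf / (n - np.arange(n))


def vacf_estimate(traj, lags=None) -> ObservableCurve:
    """Time-averaged velocity autocorrelation <U(t0+Delta) . U(t0)>.

    Velocities are taken from the trajectory when present, otherwise by
    central differences.  Cv(0) estimates d kB T / M for thermalized input.
    Ensemble-averages over a list of trajectories.
    """
    trajs = _as_traj_list(traj)
    dt = trajs[0].dt
    n = len(trajs[0])
    if lags is None:
        idx = np.arange(0, min(n - 1, 2000))
    else:
        lags = np.asarray(lags, dtype=float)
        idx = np.unique(np.round(lags / dt).astype(int))
        if np.any(idx < 0) or np.any(idx >= n):
            raise ParameterDomainError("lags must lie within the trajectory span")
    acc = np.zeros(len(idx))
    for tr in trajs:
        v = tr.velocities if tr.velocities is not None else tr.finite_difference_velocities()
        acc += _acf_fft(v)[idx]
    values = acc / len(trajs)
    # lag 0 is kept at a subvanishing positive abscissa so curves stay valid
    return ObservableCurve(
        np.where(idx == 0, 1e-12 * dt, idx * dt),
        values,
        "vacf",
        meta={"estimator": "time-averaged", "n_traj": len(trajs)},
    )


# ---------------------------------------------------------------------------
# derivative-based diagnostics
# ---------------------------------------------------------------------------

def _log_resample(curve: ObservableCurve, n_per_decade: int = 16):
    t, y = curve.times, curve.values
    if np.any(y <= 0):
        raise ParameterDomainError(f"{curve.kind} values must be positive for log diagnostics")
    lt = np.log(t)
    span = (lt[-1] - lt[0]) / np.log(10)
    n = max(int(span * n_per_decade) + 1, 8)
    lt_u = np.linspace(lt[0], lt[-1], n)
    ly_u = np.interp(lt_u, lt, np.log(y))
    return lt_u, ly_u


def _smoothed_dlog(curve: ObservableCurve, window: int = 7):
    """d log y / d log t by local quadratic (Savitzky-Golay) smoothing on a
    log-uniform resampling of the curve."""
    lt_u, ly_u = _log_resample(curve)
    window = min(window, len(lt_u) - (1 - len(lt_u) % 2))
    if window < 5:
        window = 5
    if window % 2 == 0:
        window += 1
    h = lt_u[1] - lt_u[0]
    dl = savgol_filter(ly_u, window, polyorder=2, deriv=1, delta=h)
    ly_s = savgol_filter(ly_u, window, polyorder=2)
    return np.exp(lt_u), np.exp(ly_s), dl


def local_exponent(curve: ObservableCurve, window: int = 7) -> ObservableCurve:
    """Local MSD exponent alpha(t) = d log MSD / d log t.

    alpha ~ 2 in the ballistic regime, 1 in the Brownian regime, between 0
    and 1 in the subdiffusive window.
    """
    if curve.kind != "msd":
        raise ParameterDomainError("local_exponent expects an MSD curve")
    t, _, alpha = _smoothed_dlog(curve, window)
    return ObservableCurve(t, alpha, "alpha", meta={"window": window})


def time_dependent_D(
    curve: ObservableCurve, dim: int = 2, d_inf: float | None = None, window: int = 7
) -> ObservableCurve:
    """Time-dependent diffusion coefficient D(t) = (1/2d) dMSD/dt.

    Computed as MSD/(2 d t) * dlogMSD/dlogt on a smoothed log-resampled
    curve.  When ``d_inf`` (same units) is given, the ratio D/D_inf is
    stored in the metadata.
    """
    if curve.kind != "msd":
        raise ParameterDomainError("time_dependent_D expects an MSD curve")
    t, y, dl = _smoothed_dlog(curve, window)
    d_vals = y * dl / (2.0 * dim * t)
    meta = {"window": window, "dim": dim}
    if d_inf is not None:
        meta["ratio_to_d_inf"] = d_vals / d_inf
        meta["d_inf"] = d_inf
    return ObservableCurve(t, d_vals, "dcoef", meta=meta)


# ---------------------------------------------------------------------------
# Gaussianity check
# ---------------------------------------------------------------------------

@dataclass
class CumulativeDistribution:
    """Empirical cumulative distribution Pi(r^2, Delta) of squared
    displacements at one lag.

    For Gaussian diffusion Pi(r^2, Delta) = 1 - exp[-r^2/(4 D_a Delta^a)],
    so -log(1 - Pi) is proportional to r^2 and its log-log slope in r is 2.
    """

    r2_grid: np.ndarray
    pi_values: np.ndarray
    lag: float
    meta: dict = field(default_factory=dict)


def cumulative_displacement_distribution(
    traj, lag: float, min_origins: int = 100
) -> CumulativeDistribution:
    """Empirical CDF of squared displacements at lag Delta over overlapping
    sliding origins (pooled over trajectories when a list is given)."""
    trajs = _as_traj_list(traj)
    dt = trajs[0].dt
    m = int(round(lag / dt))
    if abs(m * dt - lag) > 1e-6 * dt:
        raise ParameterDomainError("lag must be a multiple of the sampling step")
    if m < 1:
        raise ParameterDomainError("lag must be positive")
    r2 = []
    for tr in trajs:
        if m >= len(tr):
            raise ParameterDomainError("lag exceeds the trajectory span")
        d = tr.positions[m:] - tr.positions[:-m]
        r2.append(np.sum(d * d, axis=1))
    r2 = np.sort(np.concatenate(r2))
    if len(r2) < min_origins:
        raise ParameterDomainError(
            f"only {len(r2)} origins at this lag; need >= {min_origins}"
        )
    # Hazen plotting positions keep Pi < 1, needed for the -log(1-Pi) tail
    pi = (np.arange(1, len(r2) + 1) - 0.5) / len(r2)
    return CumulativeDistribution(
        r2, pi, m * dt, meta={"origins": "overlapping", "n": len(r2)}
    )


def gaussianity_exponent(
    cdist: CumulativeDistribution, quantile_window=(0.1, 0.9)
) -> float:
    """Least-squares slope of log(-log(1 - Pi)) against log r.

    A slope of 2 over the central quantile window is the Gaussian
    signature; heavy-tailed displacement distributions deviate from 2.
    """
    lo, hi = quantile_window
    mask = (cdist.pi_values >= lo) & (cdist.pi_values <= hi) & (cdist.r2_grid > 0)
    if np.count_nonzero(mask) < 4:
        raise ParameterDomainError("quantile window selects too few points")
    log_r = 0.5 * np.log(cdist.r2_grid[mask])
    log_ml = np.log(-np.log1p(-cdist.pi_values[mask]))
    slope, _ = np.polyfit(log_r, log_ml, 1)
    return float(slope)


# ---------------------------------------------------------------------------
# group averages and shell selection
# ---------------------------------------------------------------------------

def mass_weighted_group_curve(curves, masses) -> ObservableCurve:
    """Mass-weighted average sum_i m_i c_i / sum_i m_i on a shared lag grid."""
    curves = list(curves)
    masses = np.asarray(masses, dtype=float)
    if len(curves) != len(masses) or len(curves) == 0:
        raise ParameterDomainError("need matching, nonempty curves and masses")
    if np.any(masses <= 0):
        raise ParameterDomainError("masses must be positive")
    t0 = curves[0].times
    for c in curves[1:]:
        if len(c.times) != len(t0) or not np.allclose(c.times, t0):
            raise ParameterDomainError("curves must share an identical lag grid")
    vals = sum(m * c.values for m, c in zip(masses, curves)) / masses.sum()
    return ObservableCurve(
        t0, vals, curves[0].kind, units=curves[0].units,
        meta={"weighting": "mass", "n_curves": len(curves)},
    )


def select_near(distance_series, threshold: float, count: int) -> np.ndarray:
    """Indices of the ``count`` particles with the largest residence time
    within ``threshold`` of the reference.

    ``distance_series`` has shape (n_frames, n_particles), nm.  Residence
    time is the fraction of frames with distance < threshold; ties break
    toward the lower particle index.
    """
    if threshold <= 0:
        raise ParameterDomainError("threshold must be positive")
    dist = np.asarray(distance_series, dtype=float)
    if dist.ndim != 2:
        raise ParameterDomainError("distance_series must be (n_frames, n_particles)")
    n_particles = dist.shape[1]
    if not (0 < count <= n_particles):
        raise ParameterDomainError(
            f"count must be in [1, {n_particles}], got {count}"
        )
    residence = np.mean(dist < threshold, axis=0)
    order = np.lexsort((np.arange(n_particles), -residence))
    return np.sort(order[:count])
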