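"""Synchrony measures: phase velocities, Kuramoto order parameter, coherence.

The geometric phase of a node is the quadrant-aware arctangent of (v, u).
Because of the FHN slow-fast structure the geometric phase advances very
unevenly along the limit cycle; the dynamical phase theta is the monotone
reparameterization theta(phi) = 2*pi*t(phi)/T that advances at a constant
rate on the unperturbed cycle. All population measures (Kuramoto order
parameter R, stimulus coherence gamma) are computed from dynamical phases,
so fluctuations of R reflect genuine changes of synchrony rather than
slow-fast artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .fhn import FHNParameters, Trajectory, natural_frequency, single_fhn_rhs

__all__ = [
    "geometric_phase",
    "DynamicalPhaseMap",
    "PhaseSeries",
    "OrderParameterSeries",
    "mean_phase_velocity",
    "spatial_mean_velocity",
    "kuramoto_order",
    "coherence_gamma",
    "pearson",
]


def geometric_phase(u, v):
    """Quadrant-aware geometric phase arctan2(v, u) in (-pi, pi]."""
    return np.arctan2(v, u)


@dataclass
class PhaseSeries:
    """Geometric and dynamical phases of a trajectory (same array shape)."""

    times: np.ndarray
    geometric: np.ndarray
    dynamical: np.ndarray


class DynamicalPhaseMap:
    """Monotone map from geometric phase to dynamical phase.

    Built by integrating one uncoupled limit cycle and tabulating the time of
    arrival t(phi) at a dense grid of geometric phases over one period T;
    theta(phi) = 2*pi*t(phi)/T. The map is the identity for a perfectly
    circular cycle and strongly non-uniform for the slow-fast FHN cycle.
    """

    def __init__(
        self,
        params: FHNParameters | None = None,
        n_grid: int = 4096,
        t_transient: float = 200.0,
    ):
        params = params or FHNParameters()
        if params.a >= 1:
            raise ValueError("excitable regime (a >= 1): no limit cycle")
        self.omega, self.period = natural_frequency(params, t_transient=1000.0)
        T = self.period
        # sample a little more than one cycle densely
        n_samp = 20 * n_grid
        sol = solve_ivp(
            single_fhn_rhs,
            (0.0, t_transient + 1.1 * T),
            [2.0, 0.0],
            method="RK45",
            rtol=params.rtol,
            atol=params.atol,
            t_eval=np.linspace(t_transient, t_transient + 1.1 * T, n_samp),
            args=(params.epsilon, params.a),
        )
        self._build(sol.t, sol.y[0], sol.y[1], n_grid)

    @classmethod
    def from_samples(cls, times, u, v, period: float, n_grid: int = 4096):
        """Build the map from externally supplied limit-cycle samples.

        ``times``, ``u``, ``v`` must cover at least one full cycle of the
        oscillation with the given period.
        """
        self = cls.__new__(cls)
        self.period = float(period)
        self.omega = 2 * np.pi / self.period
        self._build(np.asarray(times, float), np.asarray(u, float),
                    np.asarray(v, float), n_grid)
        return self

    def _build(self, times, u, v, n_grid):
        phi = np.unwrap(geometric_phase(u, v))
        sign = 1.0 if phi[-1] > phi[0] else -1.0
        phi = sign * phi
        if np.any(np.diff(phi) < -1e-6):
            raise ValueError(
                "geometric phase is not monotone along the limit cycle; "
                "the parameter regime does not admit a dynamical phase map"
            )
        if phi[-1] - phi[0] < 2 * np.pi:
            raise ValueError("samples cover less than one full cycle")
        phi = np.maximum.accumulate(phi)  # remove round-off jitter
        t = times - times[0]
        # time of arrival at uniform geometric phases covering [phi0, phi0+2pi]
        phi0 = phi[0]
        grid = np.linspace(phi0, phi0 + 2 * np.pi, n_grid + 1)
        t_of_phi = np.interp(grid, phi, t)
        # re-reference so the map covers wrapped geometric phase [-pi, pi)
        self._sign = sign
        self._phi_grid = np.mod(sign * grid[:-1] + np.pi, 2 * np.pi) - np.pi
        order = np.argsort(self._phi_grid)
        self._phi_grid = self._phi_grid[order]
        tv = (t_of_phi[:-1] - t_of_phi[0]) % self.period
        theta = (2 * np.pi * tv / self.period)[order]
        # make the table monotone across the single wrap point so linear
        # interpolation never bridges a 2*pi discontinuity
        self._theta_grid = np.unwrap(theta)

    def __call__(self, phi):
        """Dynamical phase theta in [0, 2*pi) for wrapped geometric phase(s)."""
        phi = np.mod(np.asarray(phi, dtype=float) + np.pi, 2 * np.pi) - np.pi
        # linear interpolation with periodic extension
        theta = np.interp(
            phi,
            self._phi_grid,
            self._theta_grid,
            left=self._theta_grid[-1] - 2 * np.pi,
            right=self._theta_grid[0] + 2 * np.pi,
        )
        return np.mod(theta, 2 * np.pi)

    def phases(self, traj: Trajectory) -> PhaseSeries:
        geo = geometric_phase(traj.u, traj.v)
        return PhaseSeries(traj.times, geo, self(geo))


def mean_phase_velocity(traj: Trajectory, node: int | None = None):
    """Mean phase velocity omega_k = 2*pi*M_k / Delta T per node.

    M_k counts complete 2*pi windings of the unwrapped geometric phase over
    the trajectory's time span (the fractional remainder is discarded);
    Delta T is that span in the same (dimensionless) units. With ``node``
    (0-based) a single value is returned, otherwise the full profile.
    """
    phi = np.unwrap(geometric_phase(traj.u, traj.v), axis=0)
    span = traj.times[-1] - traj.times[0]
    gain = np.abs(phi[-1] - phi[0])
    if np.any(gain < 2 * np.pi):
        raise ValueError("trajectory covers fewer than one full rotation")
    M = np.floor(gain / (2 * np.pi))
    omega = 2 * np.pi * M / span
    return omega if node is None else omega[node]


def spatial_mean_velocity(omega_k: np.ndarray) -> float:
    """Spatially averaged mean phase velocity (mean over the 90 nodes)."""
    return float(np.mean(omega_k))


@dataclass
class OrderParameterSeries:
    """Kuramoto order parameter R(t) on the trajectory time grid."""

    times: np.ndarray
    R: np.ndarray

    def __post_init__(self):
        if np.any((self.R < -1e-12) | (self.R > 1 + 1e-12)):
            raise ValueError("R must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return float(np.mean(self.R))


def kuramoto_order(theta: np.ndarray, times=None, node_axis: int = 1):
    """R(t) = |mean_k exp(i theta_k(t))| over the node axis.

    ``theta`` is typically (n_times, N) or (n_times, N, m); the modulus of
    the mean unit phasor is taken over ``node_axis``.
    """
    R = np.abs(np.exp(1j * np.asarray(theta)).mean(axis=node_axis))
    if times is None:
        return R
    return OrderParameterSeries(np.asarray(times), R)


def coherence_gamma(
    R: np.ndarray,
    t_R: np.ndarray,
    I: np.ndarray,
    t_I: np.ndarray,
) -> float:
    """Stimulus coherence gamma = (1/Delta T) * integral of R(t) I(t) dt.

    Both series must share one physical time axis spanning the input length
    Delta T; they are linearly interpolated onto the finer of the two grids
    (so that a spike-train-like I is never undersampled) and integrated by
    the trapezoidal rule. With R and I in [0, 1], gamma lies in [0, 1];
    gamma = 1 requires complete synchrony whenever the (max-normalized)
    input is at its ceiling.
    """
    t_R, t_I = np.asarray(t_R, float), np.asarray(t_I, float)
    R, I = np.asarray(R, float), np.asarray(I, float)
    if R.shape[0] != t_R.shape[0] or I.shape[0] != t_I.shape[0]:
        raise ValueError("series and time axes must have matching lengths")
    lo = max(t_R[0], t_I[0])
    hi = min(t_R[-1], t_I[-1])
    if hi <= lo:
        raise ValueError("R and I supports do not overlap")
    dt_R = np.median(np.diff(t_R))
    dt_I = np.median(np.diff(t_I))
    t = t_I if dt_I <= dt_R else t_R
    t = t[(t >= lo) & (t <= hi)]
    Ri = np.interp(t, t_R, R)
    Ii = np.interp(t, t_I, I)
    delta_t = hi - lo
    return float(np.trapezoid(Ri * Ii, t) / delta_t)


def pearson(x, y) -> float:
    """Pearson correlation coefficient of two equal-length sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if x.size < 2:
        raise ValueError("need at least two samples")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).mean())
    sy = np.sqrt((yc**2).mean())
    if sx == 0 and sy == 0:
        raise ValueError("both x and y are constant; correlation undefined")
    if sx == 0:
        raise ValueError("x is constant; correlation undefined")
    if sy == 0:
        raise ValueError("y is constant; correlation undefined")
    return float((xc * yc).mean() / (sx * sy))
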