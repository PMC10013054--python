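"""Coupled FitzHugh-Nagumo network on the hemispheric brain connectome.

Each of the 90 brain regions carries one FHN oscillator

    eps * du_k/dt = u_k - u_k^3/3 - v_k + coupling_u + C_k I(t)
         dv_k/dt = u_k + a + coupling_v

with hemisphere-dependent coupling strengths (sigma within, varsigma
between hemispheres) through a rotational 2x2 coupling matrix B(phi), and
the cochlear input signal I(t) injected into the activator of the two
auditory-cortex nodes. Time is dimensionless; the frequency-band parameter
n_b (Hz) converts between physical stimulus time and dimensionless model
time via one physical second = T * n_b time units, with T the measured
single-oscillator period.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.integrate import solve_ivp

from . import _integrate
from .cochlea import InputSignal
from .connectome import BrainNetwork

__all__ = [
    "FHNParameters",
    "coupling_matrix",
    "fhn_rhs",
    "single_fhn_rhs",
    "natural_frequency",
    "RescaledInput",
    "Trajectory",
    "FHNNetwork",
    "initial_conditions",
]


@dataclass(frozen=True)
class FHNParameters:
    """Node and coupling parameters.

    epsilon : timescale separation between fast activator and slow inhibitor.
    a : threshold; a < 1 gives self-sustained oscillations (the regime used
        throughout), a > 1 excitable behavior.
    sigma : intra-hemispheric coupling strength.
    varsigma : inter-hemispheric coupling strength.
    phi : coupling phase of the rotational matrix B(phi); pi/2 - 0.1 gives
        predominantly activator-inhibitor cross-coupling.
    """

    epsilon: float = 0.05
    a: float = 0.5
    sigma: float = 0.7
    varsigma: float = 0.15
    phi: float = np.pi / 2 - 0.1
    rtol: float = 1e-7
    atol: float = 1e-9

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.a >= 1:
            warnings.warn(
                f"a = {self.a} >= 1: excitable regime, no self-sustained oscillations"
            )


def coupling_matrix(phi: float) -> np.ndarray:
    """Rotational coupling matrix B = [[cos phi, sin phi], [-sin phi, cos phi]]."""
    return np.array(
        [[np.cos(phi), np.sin(phi)], [-np.sin(phi), np.cos(phi)]]
    )


def single_fhn_rhs(t, y, epsilon: float, a: float):
    """Vector field of one uncoupled FHN oscillator, y = (u, v)."""
    u, v = y
    return [(u - u**3 / 3 - v) / epsilon, u + a]


def fhn_rhs(
    t: float,
    state: np.ndarray,
    network: BrainNetwork,
    params: FHNParameters,
    scheme: np.ndarray | None = None,
    input_value: float = 0.0,
) -> np.ndarray:
    """Reference (vectorized numpy) evaluation of the network vector field.

    ``state`` is the flat vector [u_1..u_N, v_1..v_N]. The coupling sum of
    node k runs with strength sigma over nodes of k's own hemisphere and
    varsigma over the opposite hemisphere. ``input_value`` is I(t) at this
    instant, injected at the auditory nodes only (activator equation).
    """
    if scheme is None:
        scheme = coupling_matrix(params.phi)
    N = network.n_nodes
    state = np.asarray(state, dtype=float)
    if state.shape != (2 * N,):
        raise ValueError(f"state must have shape ({2 * N},)")
    if not np.all(np.isfinite(state)):
        raise FloatingPointError("non-finite state")
    u, v = state[:N], state[N:]
    same = network.hemisphere_mask[:, None] == network.hemisphere_mask[None, :]
    W = np.where(same, params.sigma, params.varsigma) * network.adjacency
    rowsum = W.sum(axis=1)
    pu = W @ u - rowsum * u
    pv = W @ v - rowsum * v
    (Buu, Buv), (Bvu, Bvv) = scheme
    du = (
        u - u**3 / 3 - v + Buu * pu + Buv * pv + network.input_mask * input_value
    ) / params.epsilon
    dv = u + params.a + Bvu * pu + Bvv * pv
    return np.concatenate([du, dv])


def natural_frequency(
    params: FHNParameters | None = None,
    t_transient: float = 1000.0,
    n_cycles: int = 120,
    initial_state=(2.0, 0.0),
) -> tuple:
    """Natural angular frequency and period of one uncoupled FHN oscillator.

    Integrates a single oscillator (scipy RK45) past a transient and measures
    the mean inter-cycle interval over at least ``n_cycles`` complete 2*pi
    windings of the unwrapped geometric phase. Returns (omega, T). Any
    ``initial_state`` off the fixed point converges to the same limit cycle.
    """
    if params is None:
        params = FHNParameters()
    if params.a >= 1:
        raise ValueError(
            f"a = {params.a} >= 1: excitable regime, no limit cycle to measure"
        )
    # rough period guess to size the measurement window
    t_meas = 3.0 * (n_cycles + 2)
    n_grid = int(t_meas * 200)
    sol = solve_ivp(
        single_fhn_rhs,
        (0.0, t_transient + t_meas),
        list(initial_state),
        method="RK45",
        rtol=params.rtol,
        atol=params.atol,
        t_eval=np.linspace(t_transient, t_transient + t_meas, n_grid),
        args=(params.epsilon, params.a),
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"integration failed: {sol.message}")
    phase = np.unwrap(np.arctan2(sol.y[1], sol.y[0]))
    total = phase[-1] - phase[0]
    if abs(total) < 2 * np.pi * n_cycles:
        raise RuntimeError("measurement window covered too few cycles")
    # times of complete windings, by inverse interpolation of the phase
    sgn = np.sign(total)
    ph = sgn * phase
    k = np.arange(np.ceil(ph[0] / (2 * np.pi)) + 1, np.floor(ph[-1] / (2 * np.pi)))
    crossings = np.interp(k * 2 * np.pi, ph, sol.t)
    T = float(np.diff(crossings).mean())
    return 2 * np.pi / T, T


class RescaledInput:
    """The cochlear input signal I(t) on the dimensionless time axis.

    Physical time t_s maps to t_sim = T * n_b * t_s (T the measured FHN
    period, n_b the frequency-band parameter in Hz). The 192 kHz signal is
    decimated to at most ``samples_per_period`` samples per FHN period by
    summing the spike mass per bin and re-normalizing to max 1, then
    evaluated as a zero-order hold; outside the support the input is zero.
    """

    def __init__(
        self,
        signal: InputSignal,
        n_b: float,
        period: float,
        samples_per_period: int = 10,
        t_start: float = 0.0,
    ):
        if n_b <= 0:
            raise ValueError("n_b must be positive")
        self.n_b = float(n_b)
        self.period = float(period)
        self.t_start = float(t_start)
        self.time_scale = self.period * self.n_b  # sim units per second
        # decimate by accumulating spike mass per coarse bin, then restore the
        # max-1 normalization contract at the drive resolution (the same
        # construction as I(t) itself, at the coarser rate)
        target_rate = samples_per_period * n_b  # Hz
        factor = max(1, int(round(signal.sample_rate / target_rate)))
        vals = signal.values
        n_keep = (vals.size // factor) * factor
        if factor > 1:
            pooled = vals[:n_keep].reshape(-1, factor).sum(axis=1)
            tail = vals[n_keep:]
            if tail.size:
                pooled = np.append(pooled, tail.sum())
        else:
            pooled = vals.copy()
        peak = pooled.max()
        if peak > 0:
            pooled = pooled / peak
        self.values = np.ascontiguousarray(pooled)
        self.dt_phys = factor / signal.sample_rate
        self.dt_sim = self.dt_phys * self.time_scale
        self.duration_phys = signal.duration
        self.duration_sim = signal.duration * self.time_scale

    def __call__(self, t_sim):
        """Zero-order-hold evaluation at dimensionless time(s); 0 outside."""
        t_sim = np.asarray(t_sim, dtype=float)
        idx = np.floor((t_sim - self.t_start) / self.dt_sim).astype(int)
        ok = (idx >= 0) & (idx < self.values.size)
        out = np.where(ok, self.values[np.clip(idx, 0, self.values.size - 1)], 0.0)
        return out if out.ndim else float(out)


@dataclass
class Trajectory:
    """Simulated node states on a uniform dimensionless time grid.

    u and v have shape (n_times, N) for a single run or (n_times, N, m) for
    an ensemble of m members. ``n_b`` is the frequency-band parameter of the
    run (Hz) and ``delta_t`` the physical input-signal length in seconds.
    """

    times: np.ndarray
    u: np.ndarray
    v: np.ndarray
    n_b: float
    delta_t: float
    period: float
    seeds: tuple = (0,)

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("trajectory contains non-finite values")

    @property
    def n_members(self) -> int:
        return 1 if self.u.ndim == 2 else self.u.shape[2]

    @property
    def times_physical(self) -> np.ndarray:
        """Time axis in seconds (input-epoch time)."""
        return self.times / (self.period * self.n_b)


def initial_conditions(seed: int, n_nodes: int = 90) -> np.ndarray:
    """(u_k, v_k) drawn uniformly on the circle u^2 + v^2 = 4 (radius 2)."""
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi, n_nodes)
    return np.concatenate([2 * np.cos(theta), 2 * np.sin(theta)])


class FHNNetwork:
    """Simulator binding a BrainNetwork to FHN node dynamics.

    Precomputes the strength-weighted coupling matrix and exposes adaptive
    RK45 integration (JIT-compiled Dormand-Prince core, ensemble-batched).
    """

    def __init__(self, network: BrainNetwork, params: FHNParameters | None = None):
        self.network = network
        self.params = params or FHNParameters()
        same = network.hemisphere_mask[:, None] == network.hemisphere_mask[None, :]
        self.W = np.ascontiguousarray(
            np.where(same, self.params.sigma, self.params.varsigma) * network.adjacency
        )
        self.rowsum = self.W.sum(axis=1)
        B = coupling_matrix(self.params.phi)
        self.Buu, self.Buv = B[0]
        self.Bvu, self.Bvv = B[1]
        self.C = network.input_mask

    # -- low-level ---------------------------------------------------------

    def integrate(self, y, t0, t1, t_eval, drive: RescaledInput | None = None):
        """Advance the flat (ensemble) state from t0 to t1; sample at t_eval.

        Returns (samples, y_final). ``y`` is [u.ravel(), v.ravel()] with
        node-major, member-minor layout.
        """
        if drive is None:
            I_vals = np.empty(0)
            I_dt, I_t0 = 1.0, 0.0
        else:
            I_vals, I_dt, I_t0 = drive.values, drive.dt_sim, drive.t_start
        out, y_end, status = _integrate.integrate_fhn(
            np.ascontiguousarray(y, dtype=float),
            float(t0),
            float(t1),
            np.ascontiguousarray(t_eval, dtype=float),
            self.W,
            self.rowsum,
            self.Buu,
            self.Buv,
            self.Bvu,
            self.Bvv,
            self.params.epsilon,
            self.params.a,
            self.C,
            I_vals,
            I_dt,
            I_t0,
            self.params.rtol,
            self.params.atol,
        )
        if status == 1:
            raise FloatingPointError("integration diverged (non-finite state)")
        if status == 2:
            raise RuntimeError("integration stalled: step size underflow")
        return out, y_end

    # -- high-level --------------------------------------------------------

    def simulate(
        self,
        input_signal: InputSignal | None = None,
        n_b: float = 30.0,
        seeds=0,
        t_transient: float = 200.0,
        duration: float | None = None,
        samples_per_period: int = 20,
        period: float | None = None,
    ) -> Trajectory:
        """Transient with I=0, then the driven epoch; states on a uniform grid.

        ``seeds`` may be a single int or a sequence (ensemble run: members
        share the network and input but draw independent initial conditions
        on the circle of radius 2). ``duration`` (dimensionless) overrides
        the input-signal length; without input it must be given.
        """
        scalar = np.isscalar(seeds)
        seed_list = (int(seeds),) if scalar else tuple(int(s) for s in seeds)
        m = len(seed_list)
        N = self.network.n_nodes
        if period is None:
            period = natural_frequency(self.params)[1]
        drive = None
        if input_signal is not None:
            drive = RescaledInput(input_signal, n_b, period, t_start=0.0)
            if duration is None:
                duration = drive.duration_sim
        if duration is None:
            raise ValueError("duration must be given when no input signal is supplied")

        ics = np.stack([initial_conditions(s, N) for s in seed_list], axis=-1)
        # (2N, m) -> flat [u(N,m), v(N,m)]
        y = np.concatenate([ics[:N].ravel(), ics[N:].ravel()])

        if t_transient > 0:
            _, y = self.integrate(y, -t_transient, 0.0, np.empty(0), None)
        dt_out = period / samples_per_period
        t_eval = np.arange(0.0, duration + dt_out / 2, dt_out)
        t_eval = t_eval[t_eval <= duration + 1e-12]
        out, _ = self.integrate(y, 0.0, float(duration), t_eval, drive)
        u = out[:, : N * m].reshape(-1, N, m)
        v = out[:, N * m :].reshape(-1, N, m)
        if scalar:
            u, v = u[:, :, 0], v[:, :, 0]
        delta_t = input_signal.duration if input_signal is not None else duration / (
            period * n_b
        )
        return Trajectory(
            times=t_eval,
            u=u,
            v=v,
            n_b=float(n_b),
            delta_t=float(delta_t),
            period=float(period),
            seeds=seed_list,
        )
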