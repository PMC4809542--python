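"""Single-myocyte dynamics: a generalized FitzHugh-Nagumo (FHN) model.

The myocyte is described by two state variables, the transmembrane potential
``v_m`` (V) and a recovery variable ``w`` (V), obeying

.. math::

    \\dot v_m &= \\frac{k (v_m-v_1)(v_2-v_m)(v_m-v_3) - w
                 + \\nu h(t)}{\\varepsilon_1 c_m}, \\\\
    \\dot w   &= \\varepsilon_2 (\\beta v_m - \\gamma w + \\delta),

where ``nu h(t)`` is the pacemaker drive.  The stimulus amplitude ``nu`` is
the natural bifurcation parameter: below a lower and above an upper critical
amplitude the unique equilibrium is stable (plateau-type, excitable
behaviour); strictly between them the equilibrium is unstable and the cell
settles on a limit cycle (sustained spiking).  A stimulus that alternates
between the two regimes produces bursting-type action potentials, the
hallmark of contracting myometrium.

Closed-form discriminants decide the phase structure: ``delta1 < 0``
guarantees a unique equilibrium for every ``nu``, and ``delta2 > 0`` opens a
non-empty window of equilibrium potentials at which the Jacobian trace is
positive (a Hopf instability).  Both are computed from the model constants
alone; see :func:`discriminants` and :func:`limit_cycle_range`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "FHNParams",
    "CellState",
    "StimulusWaveform",
    "BifurcationResult",
    "CellTrace",
    "DEFAULT_CELL",
    "fhn_rhs",
    "equilibrium_stimulus",
    "equilibrium_potential",
    "jacobian",
    "discriminants",
    "limit_cycle_range",
    "classify_stimulus",
    "resting_potential",
    "simulate_cell",
    "spike_times",
    "spike_frequency",
    "burst_onsets",
    "hopf_frequency",
    "bifurcation_diagram",
]

#: Spike-detection threshold (V): halfway between rest (~ -56 mV) and the
#: spike plateau (~ -25 mV).
SPIKE_THRESHOLD = -0.035

#: Refractory lockout for spike detection (s).
SPIKE_REFRACTORY = 0.2

_REAL_ROOT_IMAG_TOL = 1e-9


@dataclass(frozen=True)
class FHNParams:
    """Constants of the generalized FHN myocyte.

    Units: ``c_m`` F/m^2, ``eps1`` Ohm*m^2, ``eps2`` 1/S, ``v1 > v2 > v3`` V
    (the roots of the cubic ionic current), ``k`` 1/V^2, ``delta`` V;
    ``beta`` and ``gamma`` are dimensionless recovery coefficients.
    """

    c_m: float = 0.01
    eps1: float = 10.0
    eps2: float = 10.0
    v1: float = -0.02
    v2: float = -0.04
    v3: float = -0.065
    k: float = 7000.0
    beta: float = 1.0
    gamma: float = 0.1
    delta: float = 0.052

    def __post_init__(self) -> None:
        if not (self.c_m > 0 and self.eps1 > 0 and self.eps2 > 0):
            raise ValueError("c_m, eps1 and eps2 must be positive")
        if not (self.k > 0 and self.gamma > 0):
            raise ValueError("k and gamma must be positive")
        if not (self.v3 < self.v2 < self.v1):
            raise ValueError("cubic root ordering v3 < v2 < v1 violated")

    def cubic(self, v_m):
        """Ionic cubic ``(v_m - v1)(v2 - v_m)(v_m - v3)`` (V^3)."""
        return (v_m - self.v1) * (self.v2 - v_m) * (v_m - self.v3)

    def with_scales(self, eps1: float, eps2: float) -> "FHNParams":
        """Copy with new time-scale parameters, all else unchanged."""
        return replace(self, eps1=eps1, eps2=eps2)


#: Published myometrium parameter set used throughout the package.
DEFAULT_CELL = FHNParams()


@dataclass(frozen=True)
class CellState:
    """Instantaneous state ``(v_m, w)`` of one myocyte, both in volts."""

    v_m: float
    w: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.v_m) and math.isfinite(self.w)):
            raise ValueError("non-finite cell state (integrator blow-up?)")

    def as_array(self) -> np.ndarray:
        return np.array([self.v_m, self.w])


@dataclass(frozen=True)
class StimulusWaveform:
    """Pacemaker drive ``nu * h(t)``.

    ``kind`` is one of ``none``, ``constant``, ``sinusoid`` or
    ``periodic_heaviside``.  ``amplitude`` is the value ``nu`` entering the
    voltage equation directly (the 1/eps1 pacemaker scaling is part of the
    equation, not of the stored amplitude).  ``period`` and ``duration`` are
    in seconds; ``phase`` shifts the waveform in time.
    """

    kind: str = "none"
    amplitude: float = 0.0
    period: float = 0.0
    duration: float = 0.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        kinds = {"none", "constant", "sinusoid", "periodic_heaviside"}
        if self.kind not in kinds:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.kind in {"sinusoid", "periodic_heaviside"} and self.period <= 0:
            raise ValueError("periodic stimulus requires period > 0")
        if self.kind == "periodic_heaviside" and not (
            0 < self.duration <= self.period
        ):
            raise ValueError("need 0 < duration <= period")

    def __call__(self, t: float) -> float:
        """Drive ``nu * h(t)`` at time ``t``."""
        if self.kind == "none":
            return 0.0
        if self.kind == "constant":
            return self.amplitude
        if self.kind == "sinusoid":
            return self.amplitude * math.sin(
                2.0 * math.pi * (t - self.phase) / self.period
            )
        # periodic heaviside: on for `duration` at the start of each period
        return self.amplitude if ((t - self.phase) % self.period) < self.duration else 0.0

    def breakpoints(self, t0: float, t1: float) -> list[float]:
        """Discontinuity times in ``(t0, t1)``; empty for smooth kinds."""
        if self.kind != "periodic_heaviside":
            return []
        out = []
        n = math.floor((t0 - self.phase) / self.period)
        while True:
            base = self.phase + n * self.period
            for edge in (base, base + self.duration):
                if t0 < edge < t1:
                    out.append(edge)
            if base > t1:
                break
            n += 1
        return sorted(set(out))


@dataclass(frozen=True)
class BifurcationResult:
    """Discriminants, equilibrium bounds and the limit-cycle stimulus window.

    ``nu_low``/``nu_high`` are NaN when the window is empty (``delta2 <= 0``).
    """

    delta1: float
    delta2: float
    vm_star_low: float
    vm_star_high: float
    nu_low: float
    nu_high: float

    @property
    def window(self) -> tuple[float, float] | None:
        if math.isnan(self.nu_low):
            return None
        return (self.nu_low, self.nu_high)


@dataclass(frozen=True)
class CellTrace:
    """Sampled trajectory of one myocyte."""

    t: np.ndarray
    v_m: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, float)
        if not (len(t) == len(self.v_m) == len(self.w)):
            raise ValueError("trace arrays must have equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time grid must be strictly increasing")


def fhn_rhs(
    state: CellState | Sequence[float],
    t: float,
    params: FHNParams,
    stim: StimulusWaveform | None = None,
) -> tuple[float, float]:
    """Time derivative ``(dv_m/dt, dw/dt)`` of the FHN system."""
    if isinstance(state, CellState):
        v, w = state.v_m, state.w
    else:
        v, w = float(state[0]), float(state[1])
    if not (math.isfinite(v) and math.isfinite(w)):
        raise FloatingPointError("non-finite state passed to fhn_rhs")
    nu = stim(t) if stim is not None else 0.0
    dv = (params.k * params.cubic(v) - w + nu) / (params.eps1 * params.c_m)
    dw = params.eps2 * (params.beta * v - params.gamma * w + params.delta)
    return dv, dw


def equilibrium_stimulus(vm_star, params: FHNParams):
    """Stimulus amplitude ``nu`` whose equilibrium potential is ``vm_star``.

    The equilibrium condition of the FHN system, with ``w`` eliminated via
    its nullcline ``w = (beta vm + delta)/gamma``, inverts to

    ``nu(vm*) = -k (vm*-v1)(v2-vm*)(vm*-v3) + (beta vm* + delta)/gamma``.
    """
    vm_star = np.asarray(vm_star, float)
    nu = -params.k * params.cubic(vm_star) + (
        params.beta * vm_star + params.delta
    ) / params.gamma
    return float(nu) if nu.ndim == 0 else nu


def _nu_polynomial(params: FHNParams) -> np.ndarray:
    """Ascending coefficients of ``nu(v)`` as a cubic polynomial in ``v``."""
    # -k (v-v1)(v2-v)(v-v3) = k (v-v1)(v-v2)(v-v3)
    mono = np.polynomial.polynomial.polyfromroots(
        [params.v1, params.v2, params.v3]
    ) * params.k
    mono[0] += params.delta / params.gamma
    mono[1] += params.beta / params.gamma
    return mono


def equilibrium_potential(nu: float, params: FHNParams) -> float:
    """Unique equilibrium potential at stimulus amplitude ``nu``.

    Requires ``delta1 < 0`` (monotone ``nu(v)``); roots come from the cubic
    companion matrix, the real root selected by smallest imaginary magnitude.
    """
    d1, _ = discriminants(params)
    if d1 >= 0:
        raise ValueError(
            "delta1 >= 0: multiple equilibria possible, analysis invalid"
        )
    coeffs = _nu_polynomial(params)
    coeffs[0] -= nu
    roots = np.roots(coeffs[::-1])
    best = roots[np.argmin(np.abs(roots.imag))]
    if abs(best.imag) > _REAL_ROOT_IMAG_TOL:
        raise ArithmeticError("no real equilibrium root found")
    return float(best.real)


def jacobian(vm_star: float, params: FHNParams) -> np.ndarray:
    """2x2 Jacobian of the FHN vector field at ``(vm*, w*)``."""
    p = params
    # d/dv [ (v-v1)(v2-v)(v-v3) ]
    dcubic = (
        (p.v2 - vm_star) * (vm_star - p.v3)
        - (vm_star - p.v1) * (vm_star - p.v3)
        + (vm_star - p.v1) * (p.v2 - vm_star)
    )
    a = p.k * dcubic / (p.eps1 * p.c_m)
    b = -1.0 / (p.eps1 * p.c_m)
    c = p.eps2 * p.beta
    d = -p.eps2 * p.gamma
    return np.array([[a, b], [c, d]])


def discriminants(params: FHNParams) -> tuple[float, float]:
    """Discriminants ``(delta1, delta2)`` of the bifurcation analysis.

    ``delta1 < 0`` guarantees uniqueness of the equilibrium for every
    stimulus amplitude; ``delta2 > 0`` opens a window of equilibrium
    potentials with a sign-changing Jacobian trace (Hopf instability).
    """
    p = params
    s = p.v1 + p.v2 + p.v3
    q = p.v1 * p.v2 + p.v1 * p.v3 + p.v2 * p.v3
    base = s * s - 3.0 * q
    delta1 = base - 3.0 * p.beta / (p.k * p.gamma)
    delta2 = base - 3.0 * p.eps1 * p.eps2 * p.c_m * p.gamma / p.k
    return delta1, delta2


def bifurcation_result(params: FHNParams) -> BifurcationResult:
    """Full bifurcation summary: discriminants, bounds and stimulus window."""
    delta1, delta2 = discriminants(params)
    if delta1 >= 0:
        raise ValueError(
            "delta1 >= 0: multiple equilibria possible, analysis invalid"
        )
    if delta2 <= 0:
        nan = float("nan")
        return BifurcationResult(delta1, delta2, nan, nan, nan, nan)
    s = params.v1 + params.v2 + params.v3
    lo = (s - math.sqrt(delta2)) / 3.0
    hi = (s + math.sqrt(delta2)) / 3.0
    nus = sorted((equilibrium_stimulus(lo, params), equilibrium_stimulus(hi, params)))
    return BifurcationResult(delta1, delta2, lo, hi, nus[0], nus[1])


def limit_cycle_range(params: FHNParams) -> tuple[float, float] | None:
    """Stimulus-amplitude window producing a limit cycle, or None if empty."""
    return bifurcation_result(params).window


def classify_stimulus(nu: float, params: FHNParams) -> str:
    """``"limit_cycle"`` or ``"stable_equilibrium"`` at amplitude ``nu``.

    The unique equilibrium is located and its Jacobian eigenvalues examined;
    a strictly positive real part means the trajectory is repelled onto the
    surrounding limit cycle.
    """
    vm_star = equilibrium_potential(nu, params)
    eig = np.linalg.eigvals(jacobian(vm_star, params))
    return "limit_cycle" if np.max(eig.real) > 0 else "stable_equilibrium"


def resting_potential(params: FHNParams) -> float:
    """Equilibrium potential at zero stimulus (V), verified stable."""
    vm = equilibrium_potential(0.0, params)
    eig = np.linalg.eigvals(jacobian(vm, params))
    if np.max(eig.real) > 0:
        raise ArithmeticError("zero-stimulus equilibrium is not stable")
    return vm


def resting_state(params: FHNParams) -> CellState:
    """Resting equilibrium ``(v_m, w)`` of the unstimulated cell."""
    vm = resting_potential(params)
    w = (params.beta * vm + params.delta) / params.gamma
    return CellState(vm, w)


def hopf_frequency(params: FHNParams, nu: float) -> float:
    """Natural angular frequency (rad/s) of the linearization at ``nu``.

    Returns ``sqrt(det J)`` at the equilibrium -- the modulus of the
    complex-conjugate eigenvalue pair, equal to its imaginary part exactly
    at the bifurcation where the real part vanishes.  Because the
    equilibrium potential depends only on ``nu``, this frequency scales
    exactly as ``sqrt(eps2/eps1)`` with the time-scale parameters.
    """
    vm_star = equilibrium_potential(nu, params)
    det = float(np.linalg.det(jacobian(vm_star, params)))
    if det <= 0.0:
        raise ArithmeticError("no oscillatory linearization at this nu")
    return math.sqrt(det)


def simulate_cell(
    params: FHNParams,
    stim: StimulusWaveform,
    duration: float,
    initial: CellState | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    sample_rate: float = 1000.0,
) -> CellTrace:
    """Integrate the FHN system for ``duration`` seconds.

    Integration uses an adaptive solver with automatic stiffness switching
    (LSODA), restarted at stimulus discontinuities so that step control never
    smears a heaviside edge.  The trace is sampled on a uniform grid.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if initial is None:
        initial = resting_state(params)
    edges = [0.0, *stim.breakpoints(0.0, duration), duration]

    def rhs(t, y):
        nu = stim(t)
        v, w = y
        dv = (params.k * params.cubic(v) - w + nu) / (params.eps1 * params.c_m)
        dw = params.eps2 * (
            params.beta * v - params.gamma * w + params.delta
        )
        return (dv, dw)

    n = max(2, int(round(duration * sample_rate)) + 1)
    t_grid = np.linspace(0.0, duration, n)
    t_all, v_all, w_all = [], [], []
    y = initial.as_array()
    for a, b in zip(edges[:-1], edges[1:]):
        interior = t_grid[(t_grid > a) & (t_grid < b)]
        t_eval = np.concatenate([[a], interior, [b]])
        sol = solve_ivp(
            rhs, (a, b), y, method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval
        )
        if not sol.success:
            raise RuntimeError(
                f"cell integration failed on [{a:g}, {b:g}] s: {sol.message}"
            )
        t_all.append(sol.t)
        v_all.append(sol.y[0])
        w_all.append(sol.y[1])
        y = sol.y[:, -1]
    t_all = np.concatenate(t_all)
    order = np.argsort(t_all, kind="stable")
    t_all = t_all[order]
    v = np.interp(t_grid, t_all, np.concatenate(v_all)[order])
    w = np.interp(t_grid, t_all, np.concatenate(w_all)[order])
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(w))):
        raise FloatingPointError("integrator produced non-finite values")
    return CellTrace(t_grid, v, w)


def spike_times(
    trace: CellTrace,
    threshold: float = SPIKE_THRESHOLD,
    refractory: float = SPIKE_REFRACTORY,
    discard_fraction: float = 0.2,
) -> np.ndarray:
    """Upward threshold-crossing times with a refractory lockout.

    The first ``discard_fraction`` of the trace is treated as transient and
    excluded from the analysis window.
    """
    t, v = trace.t, trace.v_m
    t0 = t[0] + discard_fraction * (t[-1] - t[0])
    mask = t >= t0
    t, v = t[mask], v[mask]
    if len(t) < 2:
        return np.empty(0)
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold))
    # linear interpolation of the crossing instant
    frac = (threshold - v[up]) / (v[up + 1] - v[up])
    times = t[up] + frac * (t[up + 1] - t[up])
    kept = []
    last = -np.inf
    for x in times:
        if x - last >= refractory:
            kept.append(x)
            last = x
    return np.asarray(kept)


def spike_frequency(
    trace: CellTrace,
    threshold: float = SPIKE_THRESHOLD,
    refractory: float = SPIKE_REFRACTORY,
    discard_fraction: float = 0.2,
) -> float:
    """Steady-state spike rate (spikes/s); 0 for a quiescent trace.

    With ``n >= 2`` detected spikes the rate is the reciprocal mean
    inter-spike interval ``(n-1)/(t_n - t_1)``, which is insensitive to where
    the analysis window cuts the spike train.
    """
    times = spike_times(trace, threshold, refractory, discard_fraction)
    if len(times) < 2:
        return 0.0
    return float((len(times) - 1) / (times[-1] - times[0]))


def burst_onsets(
    trace: CellTrace,
    threshold: float = SPIKE_THRESHOLD,
    gap: float = 30.0,
) -> np.ndarray:
    """Burst onset times: spikes preceded by at least ``gap`` s of silence."""
    times = spike_times(trace, threshold, discard_fraction=0.0)
    if len(times) == 0:
        return times
    gaps = np.diff(times)
    starts = np.flatnonzero(gaps > gap) + 1
    return np.concatenate([[times[0]], times[starts]])


def bifurcation_diagram(
    params: FHNParams,
    nu_grid: Iterable[float],
    settle: float = 60.0,
    window: float = 30.0,
) -> list[dict]:
    """Equilibrium branch, stability and cycle extrema over a stimulus grid.

    For each ``nu`` the unique equilibrium and its stability are reported;
    where unstable the system is integrated to its attractor and the min/max
    of ``v_m`` over the last ``window`` seconds are recorded.
    """
    rows = []
    for nu in nu_grid:
        vm_eq = equilibrium_potential(float(nu), params)
        stable = classify_stimulus(float(nu), params) == "stable_equilibrium"
        row = {
            "nu": float(nu),
            "vm_eq": vm_eq,
            "stable": stable,
            "cycle_min": math.nan,
            "cycle_max": math.nan,
        }
        if not stable:
            stim = StimulusWaveform(kind="constant", amplitude=float(nu))
            start = CellState(vm_eq + 1e-3, (params.beta * vm_eq + params.delta) / params.gamma)
            trace = simulate_cell(
                params, stim, settle + window, initial=start, sample_rate=500.0
            )
            tail = trace.t >= settle
            row["cycle_min"] = float(trace.v_m[tail].min())
            row["cycle_max"] = float(trace.v_m[tail].max())
        rows.append(row)
    return rows
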