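"""Candidate boundary-dynamics models on a periodic 1-D lattice.

Four linear/weakly-nonlinear models compete to explain the finger-like
interdigitation of epithelial cell-cell boundaries, each integrated with an
explicit Euler scheme on a uniform periodic grid:

* white noise            dh/dt = eta(x,t)
* Edwards-Wilkinson      dh/dt = dh_coeff * h_xx + eta(x,t)
* Turing (two species)   du/dt = f(u,v) + du * u_xx ; dv/dt = g(u,v) + dv * v_xx
* buckling (linear)      dh/dt = -c * h_xx - d * h_xxxx

eta is space-time white noise of variance density D: on the lattice each site
receives an independent Normal(0, D*dt/dx) increment per step, the standard
discretization that makes every Fourier mode of the Edwards-Wilkinson model an
exactly solvable discrete Ornstein-Uhlenbeck process (see
:func:`ew_stationary_mode_power`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numba
import numpy as np

from .errors import ConfigurationError, ParameterError, StabilityError

__all__ = [
    "Grid1D",
    "NoiseSpec",
    "EWParams",
    "SchnakenbergKinetics",
    "TuringParams",
    "BucklingParams",
    "Trajectory",
    "simulate_white_noise",
    "simulate_edwards_wilkinson",
    "simulate_turing",
    "simulate_buckling",
    "ew_stable_dt",
    "buckling_stable_dt",
    "turing_stable_dt",
    "ew_relaxation_time",
    "ew_stationary_mode_power",
    "ew_snapshot_ensemble",
    "turing_dispersion",
    "buckling_dispersion",
    "most_unstable_mode",
]


# --------------------------------------------------------------------------- #
# grid and parameter containers
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class Grid1D:
    """Uniform periodic 1-D grid.

    Parameters
    ----------
    n_points : int
        Number of lattice sites (>= 8).
    dx : float
        Site spacing in micrometres.
    """

    n_points: int
    dx: float
    periodic: bool = True

    def __post_init__(self):
        if self.n_points < 8:
            raise ParameterError(f"n_points must be >= 8, got {self.n_points}")
        if not self.dx > 0:
            raise ParameterError(f"dx must be positive, got {self.dx}")
        if not self.periodic:
            raise ParameterError("only periodic grids are supported")

    @property
    def length(self) -> float:
        return self.n_points * self.dx

    @property
    def x(self) -> np.ndarray:
        return np.arange(self.n_points) * self.dx

    def laplacian_eigenvalue(self, k: int | np.ndarray) -> float | np.ndarray:
        """|eigenvalue| of the discrete Laplacian for integer mode ``k``.

        The periodic three-point Laplacian acts on mode exp(2*pi*i*k*x/L) as
        multiplication by -lambda_k with

            lambda_k = (2 - 2*cos(2*pi*k/N)) / dx**2 = 4*sin(pi*k/N)**2 / dx**2
        """
        return (2.0 - 2.0 * np.cos(2.0 * np.pi * np.asarray(k) / self.n_points)) / self.dx**2


@dataclass(frozen=True)
class NoiseSpec:
    """Space-time white noise with variance density ``D`` (um^2/time per unit
    length) and an RNG seed. Sampled per site per step as Normal(0, D*dt/dx)."""

    D: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.D < 0:
            raise ParameterError(f"noise variance density D must be >= 0, got {self.D}")


@dataclass(frozen=True)
class EWParams:
    """Edwards-Wilkinson parameters: surface-tension coefficient ``dh``
    (um^2/time) plus the noise specification."""

    dh: float
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self):
        if self.dh < 0:
            raise ParameterError(f"dh must be >= 0, got {self.dh}")


@dataclass(frozen=True)
class SchnakenbergKinetics:
    """Schnakenberg activator-depleted-substrate kinetics.

        f(u, v) = alpha - u + u^2 v
        g(u, v) = beta - u^2 v

    Homogeneous steady state: u* = alpha + beta, v* = beta / (alpha + beta)^2.
    """

    alpha: float = 0.1
    beta: float = 0.9

    def f(self, u, v):
        return self.alpha - u + u * u * v

    def g(self, u, v):
        return self.beta - u * u * v

    def steady_state(self) -> tuple[float, float]:
        u0 = self.alpha + self.beta
        if u0 <= 0:
            raise ParameterError("alpha + beta must be positive")
        return u0, self.beta / u0**2

    def jacobian(self, u: float, v: float) -> np.ndarray:
        return np.array(
            [[-1.0 + 2.0 * u * v, u * u],
             [-2.0 * u * v, -u * u]]
        )


@dataclass(frozen=True)
class TuringParams:
    """Two-species reaction-diffusion parameters.

    ``kinetics`` supplies f, g, the homogeneous steady state and the Jacobian
    there; ``du``/``dv`` are the diffusion coefficients; ``perturbation_sd``
    is the amplitude of the seeded initial perturbation around the steady
    state. ``is_turing_unstable`` is evaluated analytically at construction.
    """

    du: float
    dv: float
    kinetics: SchnakenbergKinetics = field(default_factory=SchnakenbergKinetics)
    perturbation_sd: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if not (self.du > 0 and self.dv > 0):
            raise ParameterError("diffusion coefficients du, dv must be positive")
        if self.perturbation_sd < 0:
            raise ParameterError("perturbation_sd must be >= 0")

    @property
    def is_turing_unstable(self) -> bool:
        """Classic diffusion-driven-instability conditions for 2x2 kinetics:
        stable homogeneous state (tr J < 0, det J > 0) destabilized by
        diffusion (dv*fu + du*gv > 0 and (dv*fu + du*gv)^2 > 4*du*dv*det J)."""
        J = self.kinetics.jacobian(*self.kinetics.steady_state())
        tr, det = np.trace(J), float(np.linalg.det(J))
        cross = self.dv * J[0, 0] + self.du * J[1, 1]
        return tr < 0 and det > 0 and cross > 0 and cross * cross > 4.0 * self.du * self.dv * det


@dataclass(frozen=True)
class BucklingParams:
    """Linearized buckling model: ``c`` is the boundary-elongation (negative
    tension) coefficient, ``d`` the bending stiffness. Mode k grows at rate
    c*k^2 - d*k^4, maximal at k* = sqrt(c/(2d))."""

    c: float
    d: float

    def __post_init__(self):
        if self.d <= 0:
            raise ParameterError(f"bending coefficient d must be positive, got {self.d}")

    @property
    def fastest_wavenumber(self) -> float:
        """Continuum argmax of the growth rate, k* = sqrt(c/(2d)) (rad/um)."""
        return float(np.sqrt(max(self.c, 0.0) / (2.0 * self.d)))


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped stack of height profiles from one simulation run.

    ``profiles`` has shape (n_times, grid.n_points). For the two-species
    Turing model ``profiles`` holds the activator field u and
    ``aux_profiles`` the substrate field v.
    """

    grid: Grid1D
    times: np.ndarray
    profiles: np.ndarray
    model: str
    aux_profiles: Optional[np.ndarray] = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1 or np.any(np.diff(times) <= 0):
            raise ParameterError("times must be strictly increasing 1-D")
        if self.profiles.shape != (times.size, self.grid.n_points):
            raise ParameterError(
                f"profiles shape {self.profiles.shape} does not match "
                f"({times.size}, {self.grid.n_points})"
            )

    @property
    def final(self) -> np.ndarray:
        return self.profiles[-1]


# --------------------------------------------------------------------------- #
# stability bounds and helpers
# --------------------------------------------------------------------------- #

def ew_stable_dt(grid: Grid1D, dh: float, safety: float = 1.0) -> float:
    """Largest explicit-Euler step for the diffusion term: dx^2/(2*dh)."""
    if dh <= 0:
        return np.inf
    return safety * grid.dx**2 / (2.0 * dh)


def buckling_stable_dt(grid: Grid1D, params: BucklingParams, safety: float = 1.0) -> float:
    """Step bound for the fourth-order term: dx^4/(8*d)."""
    return safety * grid.dx**4 / (8.0 * params.d)


def turing_stable_dt(grid: Grid1D, params: TuringParams, safety: float = 1.0) -> float:
    """Diffusive step bound for the faster species: dx^2/(2*max(du, dv))."""
    return safety * grid.dx**2 / (2.0 * max(params.du, params.dv))


def ew_relaxation_time(grid: Grid1D, dh: float, mode: int = 1) -> float:
    """Relaxation time 1/(dh*lambda_k) of discrete mode ``mode``."""
    if dh <= 0:
        raise ParameterError("relaxation time requires dh > 0")
    return 1.0 / (dh * float(grid.laplacian_eigenvalue(mode)))


def ew_stationary_mode_power(
    grid: Grid1D, params: EWParams, dt: float, k: int | np.ndarray
) -> float | np.ndarray:
    """Exact stationary one-sided power of mode ``k`` for the Euler-discretized
    Edwards-Wilkinson chain, in the single-sine normalization (a profile
    A*sin(2*pi*k*x/L) has power A^2 at k).

    Each complex DFT mode H_k obeys H <- (1-a)H + Xi with a = dt*dh*lambda_k
    and E|Xi|^2 = N*D*dt/dx, so stationarily E|H_k|^2 = N*D*dt/(dx*a*(2-a));
    the reported power is 4*E|H_k|^2/N^2.
    """
    lam = grid.laplacian_eigenvalue(k)
    a = dt * params.dh * lam
    sigma2 = params.noise.D * dt / grid.dx
    return 4.0 * sigma2 / (grid.n_points * a * (2.0 - a))


def _check_step(dt: float, n_steps: int) -> None:
    if not dt > 0:
        raise ParameterError(f"dt must be positive, got {dt}")
    if n_steps < 1:
        raise ParameterError(f"n_steps must be >= 1, got {n_steps}")


def _lap(h: np.ndarray, dx: float) -> np.ndarray:
    """Periodic three-point Laplacian along the last axis."""
    return (np.roll(h, -1, axis=-1) - 2.0 * h + np.roll(h, 1, axis=-1)) / dx**2


@numba.njit(cache=False)
def _ew_kernel(h: np.ndarray, noise: np.ndarray, r: float) -> None:
    """In-place explicit-Euler steps h <- h + r*Lap_discrete(h) + noise[j]
    for pre-drawn noise (n_steps, n_chains, n_points); periodic wrap."""
    m, n_chains, n = noise.shape
    lap = np.empty(n)
    for j in range(m):
        for c in range(n_chains):
            row = h[c]
            for i in range(n):
                ip = i + 1 if i + 1 < n else 0
                im = i - 1 if i >= 1 else n - 1
                lap[i] = row[ip] - 2.0 * row[i] + row[im]
            for i in range(n):
                row[i] += r * lap[i] + noise[j, c, i]


def _ew_advance(
    h: np.ndarray,
    coef: float,
    dx: float,
    sd: float,
    n_steps: int,
    rng: np.random.Generator,
    chunk: int = 2048,
) -> np.ndarray:
    """Advance one or many EW chains (last axis = space) by ``n_steps`` Euler
    steps in place; noise is drawn in chunks to amortize RNG overhead."""
    h2d = h.reshape(1, -1) if h.ndim == 1 else h
    r = coef / (dx * dx)
    done = 0
    while done < n_steps:
        m = min(chunk, n_steps - done)
        noise = rng.normal(0.0, sd, (m,) + h2d.shape)
        _ew_kernel(h2d, noise, r)
        done += m
    return h


def _record_times(n_steps: int, dt: float, record_every: int) -> np.ndarray:
    idx = np.arange(0, n_steps + 1, record_every)
    if idx[-1] != n_steps:
        idx = np.append(idx, n_steps)
    return idx * dt


# --------------------------------------------------------------------------- #
# simulators
# --------------------------------------------------------------------------- #

def simulate_white_noise(
    grid: Grid1D,
    noise: NoiseSpec,
    n_steps: int,
    dt: float,
    record_every: int = 1,
    h0: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> Trajectory:
    """Integrate dh/dt = eta(x,t): pure accumulation of white-noise increments.

    Each site performs an independent Gaussian random walk with per-step
    variance D*dt/dx, so the ensemble power spectrum is flat in k at every
    time. The initial state (t=0) is recorded, then every ``record_every``
    steps and the final state.
    """
    _check_step(dt, n_steps)
    rng = np.random.default_rng(noise.seed) if rng is None else rng
    h = np.zeros(grid.n_points) if h0 is None else np.array(h0, dtype=float)
    sd = np.sqrt(noise.D * dt / grid.dx)
    out = [h.copy()]

    def advance(m: int) -> None:
        # sum of m i.i.d. increments, drawn in chunks to bound memory
        done = 0
        while done < m:
            c = min(4096, m - done)
            h[:] = h + rng.normal(0.0, sd, (c, grid.n_points)).sum(axis=0)
            done += c

    for _ in range(record_every, n_steps + 1, record_every):
        advance(record_every)
        out.append(h.copy())
    tail = n_steps % record_every
    if tail:
        advance(tail)
        out.append(h.copy())
    return Trajectory(grid, _record_times(n_steps, dt, record_every),
                      np.asarray(out), model="white_noise")


def simulate_edwards_wilkinson(
    grid: Grid1D,
    params: EWParams,
    n_steps: int,
    dt: float,
    record_every: int = 1,
    h0: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> Trajectory:
    """Integrate the Edwards-Wilkinson equation with forward Euler:

        h <- h + dt * dh * Lap(h) + Normal(0, D*dt/dx)

    Every discrete Fourier mode is an Ornstein-Uhlenbeck process relaxing at
    rate dh*lambda_k; the stationary ensemble power spectrum falls off as
    D/(dh*k^2), i.e. a log-log slope of -2.
    """
    _check_step(dt, n_steps)
    bound = ew_stable_dt(grid, params.dh)
    if dt > bound * (1 + 1e-12):
        raise StabilityError(
            f"dt={dt} violates the explicit-Euler stability bound "
            f"dx^2/(2*dh)={bound:.6g} for dh={params.dh}, dx={grid.dx}"
        )
    rng = np.random.default_rng(params.noise.seed) if rng is None else rng
    h = np.zeros(grid.n_points) if h0 is None else np.array(h0, dtype=float)
    sd = np.sqrt(params.noise.D * dt / grid.dx)
    coef = dt * params.dh
    out = [h.copy()]
    for step in range(record_every, n_steps + 1, record_every):
        _ew_advance(h, coef, grid.dx, sd, record_every, rng)
        out.append(h.copy())
    tail = n_steps % record_every
    if tail:
        _ew_advance(h, coef, grid.dx, sd, tail, rng)
        out.append(h.copy())
    return Trajectory(grid, _record_times(n_steps, dt, record_every),
                      np.asarray(out), model="ew")


def simulate_turing(
    grid: Grid1D,
    params: TuringParams,
    n_steps: int,
    dt: float,
    record_every: int = 1,
    allow_stable: bool = False,
    u0: Optional[np.ndarray] = None,
    v0: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> Trajectory:
    """Integrate the two-species reaction-diffusion system with forward Euler.

    Starts at the homogeneous steady state plus a small seeded Gaussian
    perturbation (unless ``u0``/``v0`` are given). For Turing-unstable
    parameters the activator spectrum develops a peak at the linearly most
    unstable mode; for stable parameters a :class:`ConfigurationError` is
    raised unless ``allow_stable`` is set (then the run proceeds with a
    warning — useful for decay tests).
    """
    _check_step(dt, n_steps)
    bound = turing_stable_dt(grid, params)
    if dt > bound * (1 + 1e-12):
        raise StabilityError(
            f"dt={dt} violates the diffusive stability bound "
            f"dx^2/(2*max(du,dv))={bound:.6g}"
        )
    if not params.is_turing_unstable:
        if not allow_stable:
            raise ConfigurationError(
                "parameters do not satisfy the Turing instability conditions; "
                "pass allow_stable=True to simulate anyway"
            )
        warnings.warn("simulating with Turing-stable parameters", stacklevel=2)
    rng = np.random.default_rng(params.seed) if rng is None else rng
    us, vs = params.kinetics.steady_state()
    if u0 is None:
        u = us + rng.normal(0.0, params.perturbation_sd, grid.n_points)
    else:
        u = np.array(u0, dtype=float)
    if v0 is None:
        v = vs + rng.normal(0.0, params.perturbation_sd, grid.n_points)
    else:
        v = np.array(v0, dtype=float)
    kin = params.kinetics
    out_u, out_v = [u.copy()], [v.copy()]
    for step in range(1, n_steps + 1):
        fu = kin.f(u, v)
        gv = kin.g(u, v)
        u = u + dt * (fu + params.du * _lap(u, grid.dx))
        v = v + dt * (gv + params.dv * _lap(v, grid.dx))
        if step % record_every == 0 or step == n_steps:
            out_u.append(u.copy())
            out_v.append(v.copy())
    return Trajectory(grid, _record_times(n_steps, dt, record_every),
                      np.asarray(out_u), model="turing",
                      aux_profiles=np.asarray(out_v))


def simulate_buckling(
    grid: Grid1D,
    params: BucklingParams,
    n_steps: int,
    dt: float,
    record_every: int = 1,
    h0: Optional[np.ndarray] = None,
    seed: int = 0,
    init_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> Trajectory:
    """Integrate the linear buckling model dh/dt = -c*h_xx - d*h_xxxx.

    Deterministic dynamics; mode k grows/decays at the discrete rate
    c*lambda_k - d*lambda_k^2. With ``init_sd`` > 0 the run starts from small
    seeded Gaussian noise (the generic onset-of-buckling initial condition).
    """
    _check_step(dt, n_steps)
    bound = buckling_stable_dt(grid, params)
    if dt > bound * (1 + 1e-12):
        raise StabilityError(
            f"dt={dt} violates the fourth-order stability bound "
            f"dx^4/(8*d)={bound:.6g}"
        )
    if h0 is not None:
        h = np.array(h0, dtype=float)
    elif init_sd > 0:
        rng = np.random.default_rng(seed) if rng is None else rng
        h = rng.normal(0.0, init_sd, grid.n_points)
    else:
        h = np.zeros(grid.n_points)
    out = [h.copy()]
    for step in range(1, n_steps + 1):
        lap = _lap(h, grid.dx)
        h = h + dt * (-params.c * lap - params.d * _lap(lap, grid.dx))
        if step % record_every == 0 or step == n_steps:
            out.append(h.copy())
    return Trajectory(grid, _record_times(n_steps, dt, record_every),
                      np.asarray(out), model="buckling")


# --------------------------------------------------------------------------- #
# dispersion relations (linear-stability oracles for the pattern models)
# --------------------------------------------------------------------------- #

def turing_dispersion(grid: Grid1D, params: TuringParams) -> np.ndarray:
    """Largest real part of the linear growth rate per integer mode k=0..N/2,
    from the Jacobian of the kinetics at the homogeneous steady state with the
    discrete Laplacian eigenvalues substituted for q^2."""
    J = params.kinetics.jacobian(*params.kinetics.steady_state())
    ks = np.arange(grid.n_points // 2 + 1)
    lam = grid.laplacian_eigenvalue(ks)
    rates = np.empty(ks.size)
    for i, l in enumerate(np.atleast_1d(lam)):
        A = J - np.diag([params.du * l, params.dv * l])
        rates[i] = np.max(np.linalg.eigvals(A).real)
    return rates


def buckling_dispersion(grid: Grid1D, params: BucklingParams) -> np.ndarray:
    """Discrete growth rate c*lambda_k - d*lambda_k^2 per integer mode."""
    lam = grid.laplacian_eigenvalue(np.arange(grid.n_points // 2 + 1))
    return params.c * lam - params.d * lam * lam


def most_unstable_mode(rates: np.ndarray) -> int:
    """Integer mode index (k >= 1) maximizing the linear growth rate."""
    return int(np.argmax(rates[1:]) + 1)


# --------------------------------------------------------------------------- #
# stationary snapshot sampling
# --------------------------------------------------------------------------- #

def ew_snapshot_ensemble(
    grid: Grid1D,
    params: EWParams,
    dt: float,
    n_snapshots: int,
    burn_relax: float = 10.0,
    spacing_mode: int = 2,
    rng: Optional[np.random.Generator] = None,
    n_chains: int = 1,
) -> np.ndarray:
    """Well-separated stationary Edwards-Wilkinson snapshots.

    Runs ``n_chains`` independent chains (vectorized), burns each in for
    ``burn_relax`` times the slowest-mode relaxation time 1/(dh*lambda_1),
    then records states spaced by the relaxation time of mode
    ``spacing_mode`` (the slowest mode inside the usual fit window) until
    ``n_snapshots`` have been collected. Returns (n_snapshots, n_points).
    """
    if params.dh <= 0:
        raise ParameterError("snapshot ensemble requires dh > 0")
    if dt > ew_stable_dt(grid, params.dh) * (1 + 1e-12):
        raise StabilityError(
            f"dt={dt} violates the stability bound "
            f"dx^2/(2*dh)={ew_stable_dt(grid, params.dh):.6g}"
        )
    if n_snapshots < 1:
        raise ParameterError("n_snapshots must be >= 1")
    rng = np.random.default_rng(params.noise.seed) if rng is None else rng
    burn_steps = max(1, int(np.ceil(burn_relax * ew_relaxation_time(grid, params.dh, 1) / dt)))
    spacing_steps = max(1, int(np.ceil(ew_relaxation_time(grid, params.dh, spacing_mode) / dt)))
    sd = np.sqrt(params.noise.D * dt / grid.dx)
    coef = dt * params.dh
    state = np.zeros((n_chains, grid.n_points))
    _ew_advance(state, coef, grid.dx, sd, burn_steps, rng)
    rounds = -(-n_snapshots // n_chains)
    snaps = np.empty((rounds, n_chains, grid.n_points))
    for r in range(rounds):
        _ew_advance(state, coef, grid.dx, sd, spacing_steps, rng)
        snaps[r] = state
    return snaps.reshape(-1, grid.n_points)[:n_snapshots]
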