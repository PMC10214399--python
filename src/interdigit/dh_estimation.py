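"""Estimation of the boundary diffusion coefficient d_h.

If each point of a cell boundary obeys the Edwards-Wilkinson equation, the
frame-to-frame displacement at site i is

    dh_i = d_h * Lap(h)_i * dt + noise increment,

where the noise increment is zero-mean and independent of the current
profile. Averaging over many data points (all interior sites of all segments
and all transitions) eliminates the noise term; the pooled least-squares
estimator

    d_h^ = sum_ij Lap(h)_ij * delta_h_ij / (dt * sum_ij Lap(h)_ij^2)

is therefore unbiased. The standard error is obtained by bootstrap over
segments (sites within a segment are correlated, segments are not).

A second route to d_h goes through boundary mechanics: a boundary of
thickness L_h, Young's modulus E and compression ratio a, moving against a
drag c', shortens with an effective diffusion coefficient
d_h = (1/a - 1) * L_h * E / c'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, ParameterError

__all__ = [
    "ProfileSeries",
    "MechanicalParams",
    "DhEstimate",
    "estimate_dh",
    "estimate_dh_per_segment",
    "dh_from_mechanics",
]


@dataclass(frozen=True)
class ProfileSeries:
    """Height profiles of one boundary segment at uniformly spaced times.

    ``profiles`` has shape (n_times, n_sites); sites are spaced ``dx`` um,
    frames ``delta_t`` apart (in whatever time unit the caller uses — the
    estimate comes out in um^2 per that unit).
    """

    times: np.ndarray
    profiles: np.ndarray
    dx: float
    segment_id: str | int = 0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.profiles, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ParameterError("need >= 2 timepoints")
        dts = np.diff(t)
        if np.any(dts <= 0):
            raise ParameterError("times must be strictly increasing")
        if not np.allclose(dts, dts[0], rtol=1e-8, atol=0.0):
            raise ParameterError("timepoints must be uniformly spaced")
        if p.shape != (t.size, p.shape[1]) or p.shape[1] < 3:
            raise ParameterError("profiles must be (n_times, n_sites>=3)")
        if not self.dx > 0:
            raise ParameterError("dx must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "profiles", p)

    @property
    def delta_t(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class MechanicalParams:
    """Mechanical description of a boundary: compression ratio ``a`` in
    (0, 1], thickness ``L_h`` (um), Young's modulus ``E`` (Pa) and drag
    coefficient ``c_prime`` (units chosen so d_h comes out in um^2/s)."""

    a: float
    L_h: float
    E: float
    c_prime: float

    def __post_init__(self):
        for name in ("a", "L_h", "E", "c_prime"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)}")
        if self.a > 1:
            raise ParameterError(f"compression ratio a must be <= 1, got {self.a}")


@dataclass(frozen=True)
class DhEstimate:
    dh: float
    se: float
    n_segments: int
    delta_t: float
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def noise_dominated(self) -> bool:
        return "noise_dominated" in self.flags


def _interior_laplacian(profiles: np.ndarray, dx: float) -> np.ndarray:
    """Central-difference Laplacian at interior sites (segments are not
    periodic; endpoint sites are excluded)."""
    return (profiles[:, 2:] - 2.0 * profiles[:, 1:-1] + profiles[:, :-2]) / dx**2


def _series_sums(series: ProfileSeries) -> tuple[float, float]:
    """(sum lap*delta_h, sum lap^2) over all interior sites and transitions."""
    lap = _interior_laplacian(series.profiles[:-1], series.dx)
    dh_inc = series.profiles[1:, 1:-1] - series.profiles[:-1, 1:-1]
    return float(np.sum(lap * dh_inc)), float(np.sum(lap * lap))


def _check_common_grid(series: Sequence[ProfileSeries]) -> None:
    if not series:
        raise DegenerateInputError("empty series collection")
    s0 = series[0]
    for s in series[1:]:
        if s.profiles.shape[1] != s0.profiles.shape[1] or s.dx != s0.dx:
            raise ParameterError("all series must share the spatial grid")
        if not np.isclose(s.delta_t, s0.delta_t, rtol=1e-8):
            raise ParameterError("all series must share the frame interval")


def estimate_dh(
    series: Sequence[ProfileSeries],
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> DhEstimate:
    """Pooled least-squares estimate of d_h from boundary time series.

    Pools all interior sites and frame transitions of all segments; the
    standard error is a percentile-based bootstrap SE over segments (half the
    central 68.3% interval of ``n_bootstrap`` resampled estimates). A
    negative estimate is returned as-is but flagged ``noise_dominated``.
    """
    series = list(series)
    _check_common_grid(series)
    sums = np.array([_series_sums(s) for s in series])  # (n_seg, 2)
    num, den = sums.sum(axis=0)
    if den == 0.0:
        raise DegenerateInputError(
            "Laplacian vanishes on all profiles (flat boundaries): d_h undefined"
        )
    delta_t = series[0].delta_t
    dh_hat = num / (delta_t * den)

    rng = np.random.default_rng(seed)
    n_seg = len(series)
    if n_seg > 1 and n_bootstrap > 0:
        idx = rng.integers(0, n_seg, size=(n_bootstrap, n_seg))
        boot_num = sums[:, 0][idx].sum(axis=1)
        boot_den = sums[:, 1][idx].sum(axis=1)
        ok = boot_den > 0
        boot = boot_num[ok] / (delta_t * boot_den[ok])
        lo, hi = np.percentile(boot, [15.865, 84.135])
        se = float((hi - lo) / 2.0)
    else:
        se = float("nan")

    flags = []
    if dh_hat < 0:
        flags.append("noise_dominated")
    return DhEstimate(
        dh=float(dh_hat), se=se, n_segments=n_seg,
        delta_t=delta_t, flags=tuple(flags),
    )


def estimate_dh_per_segment(series: Sequence[ProfileSeries]) -> np.ndarray:
    """Per-segment d_h estimates (no bootstrap) — the per-boundary samples
    that group comparisons between conditions operate on."""
    series = list(series)
    _check_common_grid(series)
    out = np.empty(len(series))
    for i, s in enumerate(series):
        num, den = _series_sums(s)
        if den == 0.0:
            raise DegenerateInputError(
                f"segment {s.segment_id!r}: flat profiles, d_h undefined"
            )
        out[i] = num / (s.delta_t * den)
    return out


def dh_from_mechanics(m: MechanicalParams) -> float:
    """d_h = (1/a - 1) * L_h * E / c'.

    Linear in thickness and stiffness, decreasing in the compression ratio;
    an uncompressed boundary (a = 1) does not fluctuate diffusively (d_h = 0).
    """
    return (1.0 / m.a - 1.0) * m.L_h * m.E / m.c_prime
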