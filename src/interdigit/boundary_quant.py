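"""Boundary-shape quantification.

Converts ridge-detection polylines of cell-cell boundaries into standardized
one-dimensional height functions h(x) and computes the three shape statistics
used to characterize interdigitation:

* the scaling exponent of the ensemble-averaged power spectrum <|h^(k)|^2>,
* tortuosity (arc length / chord length),
* maximal amplitude max|h(x)|,

plus nonparametric group comparisons (Mann-Whitney, Kruskal-Wallis).

Spectrum convention
-------------------
Profiles are resampled to a fixed number of samples ``n`` with both endpoints
pinned to zero; the duplicate endpoint is dropped before the DFT so the
remaining ``n-1`` samples tile one period. Amplitudes are normalized so a pure
sine A*sin(2*pi*k0*x/L) has |h^(k0)| = A; power is |h^(k)|^2 and the mean
(k=0) is excluded. Under this convention Parseval's identity reads
sum_k power(k)/2 = mean((h - mean h)^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, OverhangError, ParameterError

__all__ = [
    "Polyline",
    "HeightProfile",
    "Spectrum",
    "ScalingFit",
    "GroupComparison",
    "standardize_segment",
    "power_spectrum",
    "periodic_power_spectrum",
    "ensemble_spectrum",
    "ensemble_periodic_spectrum",
    "fit_scaling",
    "tortuosity",
    "max_amplitude",
    "group_compare",
]

DEFAULT_RESAMPLE_N = 128


@dataclass(frozen=True)
class Polyline:
    """Ordered 2-D boundary trace in micrometres, as exported by ridge
    detection: one segment id plus >= 3 distinct consecutive points."""

    segment_id: str | int
    points: np.ndarray  # (n, 2)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ParameterError("points must be an (n, 2) array")
        if pts.shape[0] < 3:
            raise ParameterError(
                f"segment {self.segment_id!r}: need >= 3 points, got {pts.shape[0]}"
            )
        if not np.all(np.isfinite(pts)):
            raise ParameterError(f"segment {self.segment_id!r}: non-finite coordinates")
        if np.any(np.all(np.diff(pts, axis=0) == 0.0, axis=1)):
            raise ParameterError(
                f"segment {self.segment_id!r}: consecutive duplicate points"
            )
        object.__setattr__(self, "points", pts)

    @property
    def arc_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    @property
    def chord_length(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))


@dataclass(frozen=True)
class HeightProfile:
    """Standardized boundary function h(x): ``n`` uniform samples over the
    chord [0, L], chord-detrended so h[0] = h[-1] = 0."""

    length: float
    h: np.ndarray

    def __post_init__(self):
        h = np.asarray(self.h, dtype=float)
        if h.ndim != 1 or h.size < 8:
            raise ParameterError("h must be 1-D with >= 8 samples")
        if not self.length > 0:
            raise ParameterError(f"length must be positive, got {self.length}")
        object.__setattr__(self, "h", h)

    @property
    def n(self) -> int:
        return self.h.size

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, self.length, self.n)


@dataclass(frozen=True)
class Spectrum:
    """One-sided power spectrum over integer wavenumbers (cycles per segment),
    k starting at 1; ``n_segments`` records whether this is a single-segment
    spectrum or an ensemble mean."""

    k: np.ndarray
    power: np.ndarray
    n_segments: int = 1

    def __post_init__(self):
        k = np.asarray(self.k, dtype=int)
        p = np.asarray(self.power, dtype=float)
        if k.shape != p.shape or k.ndim != 1:
            raise ParameterError("k and power must be matching 1-D arrays")
        if k.size and k[0] != 1:
            raise ParameterError("wavenumbers must start at k=1")
        if np.any(p < 0):
            raise ParameterError("power must be non-negative")
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "power", p)


@dataclass(frozen=True)
class ScalingFit:
    """OLS fit of log10(power) on log10(k): signed slope (``exponent``),
    half-width of its 95% CI, intercept and the fit window."""

    exponent: float
    ci95: float
    intercept: float
    k_range: tuple[int, int]
    stderr: float

    @property
    def magnitude(self) -> float:
        """|slope| — the sign-free form in which scaling exponents are
        conventionally reported."""
        return abs(self.exponent)


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    method: str
    exact: bool


# --------------------------------------------------------------------------- #
# standardization
# --------------------------------------------------------------------------- #

def standardize_segment(p: Polyline, n: int = DEFAULT_RESAMPLE_N) -> HeightProfile:
    """Rotate a polyline so its endpoint chord lies on the x-axis and resample
    the height to ``n`` uniform points.

    Raises :class:`OverhangError` if the rotated x-coordinates are not
    strictly increasing, i.e. the boundary is not a single-valued function of
    chord position (automated version of the manual removal of overhung
    segments). The chord line is subtracted so h(0) = h(L) = 0.
    """
    if n < 8:
        raise ParameterError(f"resample count n must be >= 8, got {n}")
    pts = p.points - p.points[0]
    chord = pts[-1]
    L = float(np.linalg.norm(chord))
    if L == 0.0:
        raise DegenerateInputError(
            f"segment {p.segment_id!r}: zero-length chord (closed loop)"
        )
    c, s = chord / L
    # rotate chord onto +x
    x = pts[:, 0] * c + pts[:, 1] * s
    y = -pts[:, 0] * s + pts[:, 1] * c
    if np.any(np.diff(x) <= 0.0):
        raise OverhangError(p.segment_id)
    xs = np.linspace(0.0, L, n)
    h = np.interp(xs, x, y)
    h = h - (h[0] + (h[-1] - h[0]) * xs / L)  # chord detrend (endpoints -> 0)
    return HeightProfile(length=L, h=h)


# --------------------------------------------------------------------------- #
# spectra
# --------------------------------------------------------------------------- #

def periodic_power_spectrum(values: np.ndarray) -> Spectrum:
    """One-sided power spectrum of one period of samples (no duplicated
    endpoint), mean-subtracted, in the single-sine normalization."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 8:
        raise ParameterError("need >= 8 samples in one period")
    m = v.size
    H = np.fft.rfft(v - v.mean())
    k_max = (m - 1) // 2  # exclude k=0 and (for even m) the Nyquist bin
    amp = 2.0 * np.abs(H[1 : k_max + 1]) / m
    return Spectrum(k=np.arange(1, k_max + 1), power=amp**2, n_segments=1)


def power_spectrum(hp: HeightProfile) -> Spectrum:
    """Power spectrum of a standardized profile.

    h[0] = h[-1] = 0, so dropping the duplicate endpoint leaves one period of
    the segment's periodic extension.
    """
    return periodic_power_spectrum(hp.h[:-1])


def ensemble_spectrum(profiles: Sequence[HeightProfile]) -> Spectrum:
    """Unweighted per-wavenumber mean of single-segment power spectra."""
    profiles = list(profiles)
    if not profiles:
        raise DegenerateInputError("empty profile collection")
    ns = {hp.n for hp in profiles}
    if len(ns) != 1:
        raise ParameterError(f"profiles must share the sample count, got {sorted(ns)}")
    spectra = [power_spectrum(hp) for hp in profiles]
    return Spectrum(
        k=spectra[0].k,
        power=np.mean([s.power for s in spectra], axis=0),
        n_segments=len(spectra),
    )


def ensemble_periodic_spectrum(snapshots: np.ndarray) -> Spectrum:
    """Ensemble-mean power spectrum of an array of periodic profiles
    (n_snapshots, n_points) — the natural form for simulator output."""
    snaps = np.atleast_2d(np.asarray(snapshots, dtype=float))
    if snaps.shape[0] == 0:
        raise DegenerateInputError("empty snapshot array")
    spectra = [periodic_power_spectrum(row) for row in snaps]
    return Spectrum(
        k=spectra[0].k,
        power=np.mean([s.power for s in spectra], axis=0),
        n_segments=snaps.shape[0],
    )


def default_fit_window(s: Spectrum) -> tuple[int, int]:
    """Default window [2, n/8]: k=1 is detrending-sensitive, high k carries
    resampling noise. For a spectrum of n/2 - 1 bins this is (len+1)//4."""
    return 2, max(4, (s.k.size + 1) // 4)


def fit_scaling(s: Spectrum, k_min: int = 2, k_max: int | None = None) -> ScalingFit:
    """OLS regression of log10(power) on log10(k) over k in [k_min, k_max].

    Returns the signed slope with a t-based 95% confidence half-width.
    """
    if k_max is None:
        k_max = default_fit_window(s)[1]
    if k_max > int(s.k[-1]):
        raise ParameterError(f"k_max={k_max} exceeds available k={int(s.k[-1])}")
    sel = (s.k >= k_min) & (s.k <= k_max)
    if np.count_nonzero(sel) < 4:
        raise ParameterError(
            f"fit window [{k_min}, {k_max}] holds fewer than 4 wavenumbers"
        )
    if np.any(s.power[sel] <= 0):
        raise DegenerateInputError("zero power inside the fit window")
    res = stats.linregress(np.log10(s.k[sel]), np.log10(s.power[sel]))
    dof = np.count_nonzero(sel) - 2
    tcrit = float(stats.t.ppf(0.975, dof))
    return ScalingFit(
        exponent=float(res.slope),
        ci95=tcrit * float(res.stderr),
        intercept=float(res.intercept),
        k_range=(int(k_min), int(k_max)),
        stderr=float(res.stderr),
    )


# --------------------------------------------------------------------------- #
# scalar statistics
# --------------------------------------------------------------------------- #

def tortuosity(p: Polyline) -> float:
    """Arc length / chord length; 1 for a straight segment."""
    chord = p.chord_length
    if chord == 0.0:
        raise DegenerateInputError(
            f"segment {p.segment_id!r}: zero chord, tortuosity undefined"
        )
    return p.arc_length / chord


def max_amplitude(hp: HeightProfile) -> float:
    """max_x |h(x)| of a chord-detrended profile (um)."""
    return float(np.max(np.abs(hp.h)))


# --------------------------------------------------------------------------- #
# group comparison
# --------------------------------------------------------------------------- #

def _mann_whitney_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic of sample a: #{a_i > b_j} + 0.5 * #{a_i == b_j}."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def _mann_whitney_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full enumeration of the C(n, n1)
    group labelings (valid with ties). Under exchangeability U is symmetric
    about mu = n1*n2/2; p = P(|U - mu| >= |u_obs - mu|)."""
    pooled = np.concatenate([a, b])
    n, n1 = pooled.size, a.size
    u_obs = _mann_whitney_u(a, b)
    mu = n1 * (n - n1) / 2.0
    dev = abs(u_obs - mu)
    hits = total = 0
    idx = np.arange(n)
    for comb in combinations(idx, n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(comb)] = True
        u = _mann_whitney_u(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
    return u_obs, hits / total


def group_compare(
    a: Iterable[float],
    b: Iterable[float],
    method: Literal["mann_whitney", "kruskal_wallis"] = "mann_whitney",
) -> GroupComparison:
    """Two-sided nonparametric comparison of two samples of boundary
    statistics.

    Mann-Whitney uses the exact enumeration null when the combined sample
    size is <= 12 and the normal approximation with tie correction otherwise;
    Kruskal-Wallis delegates to the chi-square approximation.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise DegenerateInputError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        raise DegenerateInputError("all values identical across both groups")
    if method == "mann_whitney":
        if a.size + b.size <= 12:
            u, p = _mann_whitney_exact(a, b)
            return GroupComparison(u, p, method, exact=True)
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return GroupComparison(float(res.statistic), float(res.pvalue), method, exact=False)
    if method == "kruskal_wallis":
        res = stats.kruskal(a, b)
        return GroupComparison(float(res.statistic), float(res.pvalue), method, exact=False)
    raise ParameterError(f"unknown method {method!r}")
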