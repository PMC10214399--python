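"""Synthetic inputs with known ground truth for every pipeline stage.

No deposited microscopy data exist for this analysis, so the generators here
emulate the three kinds of raw input the pipeline consumes:

* ridge-detection-style boundary polylines whose underlying height function
  h(x) is drawn from a chosen dynamics model (rotated and translated in the
  plane, vertex-jittered, optionally corrupted with a small loop so that the
  overhang-rejection path is exercised),
* boundary-profile time series with a known diffusion coefficient d_h,
* kymographs of Gaussian myosin-like puncta with a designed smallest-unit
  size, plus 2-D puncta scenes for threshold counting.

Every generator is seed-deterministic and returns a machine-readable ground
truth next to its data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import simulators as sim
from .boundary_quant import Polyline
from .dh_estimation import ProfileSeries
from .errors import ConfigurationError, ParameterError
from .kymograph import Kymograph

__all__ = [
    "SegmentEmulationSpec",
    "PunctaSceneSpec",
    "make_segments",
    "make_profile_series",
    "make_kymograph",
    "make_puncta_image",
]

_MODELS = ("white_noise", "ew", "turing", "buckling", "fixed_profile")

# Per-model generator defaults. Chosen to emulate day-0-like MDCK boundary
# segments: ~20 um segments with sub-micrometre interdigitation amplitude and
# pattern wavelengths of a few micrometres for the two pattern-forming models.
_MODEL_DEFAULTS = {
    "white_noise": {"D": 0.01, "t_end": 2.0, "dt": 0.01, "n_model_points": 256},
    "ew": {"dh": 1.0, "D": 0.2, "n_model_points": 256},
    "turing": {"du": 0.05, "dv": 2.0, "alpha": 0.1, "beta": 0.9,
               "t_end": 30.0, "height_scale": 1.0, "n_model_points": 256},
    "buckling": {"c": 0.243, "d": 0.049, "t_end": 20.0, "init_sd": 0.01,
                 "n_model_points": 128},
    "fixed_profile": {"n_model_points": 256},
}


@dataclass(frozen=True)
class SegmentEmulationSpec:
    """Recipe for a batch of emulated ridge-detection segments.

    ``model_params`` overrides the per-model defaults above; for
    ``fixed_profile`` it must carry ``h`` (an array on the model grid or a
    callable of x in [0, L]). ``overhang_fraction`` of the segments get a
    small loop spliced into their interior, which makes them non-single-valued
    along any chord and therefore rejected by standardization.
    """

    model: str
    n_segments: int = 100
    segment_length_um: float = 20.0
    point_spacing_um: float = 0.2
    rotation_range: float = np.pi
    jitter_sd: float = 0.02
    overhang_fraction: float = 0.0
    model_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.model not in _MODELS:
            raise ConfigurationError(
                f"unknown model {self.model!r}; expected one of {_MODELS}"
            )
        if not 0.0 <= self.overhang_fraction <= 1.0:
            raise ParameterError("overhang_fraction must be in [0, 1]")
        if self.jitter_sd < 0:
            raise ParameterError("jitter_sd must be >= 0")
        if self.n_segments < 1:
            raise ParameterError("n_segments must be >= 1")
        if not (self.segment_length_um > 0 and self.point_spacing_um > 0):
            raise ParameterError("lengths must be positive")
        if self.point_spacing_um * 2 >= self.segment_length_um:
            raise ParameterError("point spacing too coarse for the segment length")


@dataclass(frozen=True)
class PunctaSceneSpec:
    """Recipe for a 1-D line of Gaussian puncta imaged over time.

    ``mobility_sd`` is the per-frame random-walk step (um); 0 means static.
    With ``spacing_um`` set, puncta are placed periodically — an analysis
    window containing an integer number of spacings then has its spectral
    energy at the design wavenumber, and the designed smallest-unit size is
    ``spacing_um / 2``.
    """

    n_puncta: int
    radius_um: float = 0.3
    mobility_sd: float = 0.0
    intensity: float = 1.0
    background_sd: float = 0.0
    pixel_size_um: float = 0.1541
    n_pixels: int = 207
    n_frames: int = 60
    frame_interval: float = 1.0
    spacing_um: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_puncta < 0:
            raise ParameterError("n_puncta must be >= 0")
        if not self.radius_um > 0:
            raise ParameterError("radius_um must be positive")
        if self.mobility_sd < 0 or self.background_sd < 0:
            raise ParameterError("noise/mobility SDs must be >= 0")
        if self.n_pixels < 8 or self.n_frames < 1:
            raise ParameterError("need >= 8 pixels and >= 1 frame")
        if not (self.pixel_size_um > 0 and self.frame_interval > 0):
            raise ParameterError("pixel_size_um and frame_interval must be positive")
        if self.spacing_um is not None and not self.spacing_um > 0:
            raise ParameterError("spacing_um must be positive when given")

    @property
    def extent_um(self) -> float:
        return self.n_pixels * self.pixel_size_um


# --------------------------------------------------------------------------- #
# boundary segments
# --------------------------------------------------------------------------- #

def _draw_profiles(spec: SegmentEmulationSpec, rng: np.random.Generator) -> np.ndarray:
    """(n_segments, n_model) height samples from the named model on a model
    grid spanning the segment length."""
    p = {**_MODEL_DEFAULTS[spec.model], **spec.model_params}
    nm = int(p["n_model_points"])
    L = spec.segment_length_um
    grid = sim.Grid1D(nm, L / nm)
    n = spec.n_segments

    if spec.model == "fixed_profile":
        if "h" not in p:
            raise ConfigurationError("fixed_profile requires model_params['h']")
        h = p["h"]
        h = np.asarray(h(grid.x) if callable(h) else h, dtype=float)
        if h.shape != (nm,):
            raise ConfigurationError(f"fixed profile must have {nm} samples")
        return np.tile(h, (n, 1))

    if spec.model == "white_noise":
        noise = sim.NoiseSpec(D=p["D"])
        steps = max(1, int(round(p["t_end"] / p["dt"])))
        return np.stack([
            sim.simulate_white_noise(grid, noise, steps, p["dt"],
                                     record_every=steps, rng=rng).final
            for _ in range(n)
        ])

    if spec.model == "ew":
        params = sim.EWParams(dh=p["dh"], noise=sim.NoiseSpec(D=p["D"]))
        dt = 0.2 * sim.ew_stable_dt(grid, p["dh"])
        return sim.ew_snapshot_ensemble(grid, params, dt, n_snapshots=n, rng=rng)

    if spec.model == "turing":
        kin = sim.SchnakenbergKinetics(alpha=p["alpha"], beta=p["beta"])
        params = sim.TuringParams(du=p["du"], dv=p["dv"], kinetics=kin)
        dt = 0.5 * sim.turing_stable_dt(grid, params)
        steps = max(1, int(round(p["t_end"] / dt)))
        scale = p["height_scale"]
        out = np.empty((n, nm))
        for i in range(n):
            u = sim.simulate_turing(grid, params, steps, dt,
                                    record_every=steps, rng=rng).final
            out[i] = scale * (u - u.mean())
        return out

    # buckling
    params = sim.BucklingParams(c=p["c"], d=p["d"])
    dt = 0.5 * sim.buckling_stable_dt(grid, params)
    steps = max(1, int(round(p["t_end"] / dt)))
    out = np.empty((n, nm))
    for i in range(n):
        h0 = rng.normal(0.0, p["init_sd"], nm)
        out[i] = sim.simulate_buckling(grid, params, steps, dt,
                                       record_every=steps, h0=h0).final
    return out


def _insert_loop(pts: np.ndarray, rng: np.random.Generator, radius: float) -> np.ndarray:
    """Splice a full small circle into the interior of a polyline. The path
    direction sweeps 360 deg inside the loop, so the x-coordinate reverses
    under any rotation — guaranteeing overhang rejection."""
    i = int(rng.integers(pts.shape[0] // 4, 3 * pts.shape[0] // 4))
    center = pts[i] + np.array([radius, 0.0])
    theta = np.pi + 2.0 * np.pi * np.arange(1, 10) / 9.0
    loop = center + radius * np.column_stack([np.cos(theta), np.sin(theta)])
    return np.vstack([pts[: i + 1], loop, pts[i + 1 :]])


def make_segments(spec: SegmentEmulationSpec) -> tuple[list[Polyline], pd.DataFrame]:
    """Emulate a ridge-detection export: polylines plus a ground-truth table.

    Each segment's model profile is sampled at ``point_spacing_um``, embedded
    in the plane with a random rotation and translation, vertex-jittered, and
    (for the flagged fraction) corrupted with a loop. Ground truth records,
    per segment, the overhang flag and the tortuosity/amplitude of the clean
    (pre-jitter, pre-loop) embedding.
    """
    rng = np.random.default_rng(spec.seed)
    profiles = _draw_profiles(spec, rng)
    L = spec.segment_length_um
    nm = profiles.shape[1]
    x_model = np.arange(nm) * (L / nm)
    # sample points along the chord, endpoint included (periodic wrap for h(L))
    x_pts = np.arange(0.0, L + 0.5 * spec.point_spacing_um, spec.point_spacing_um)
    x_pts[-1] = min(x_pts[-1], L)
    x_wrap = np.append(x_model, L)

    n_over = int(round(spec.overhang_fraction * spec.n_segments))
    over_idx = set(rng.choice(spec.n_segments, size=n_over, replace=False).tolist())

    polylines: list[Polyline] = []
    rows = []
    for i in range(spec.n_segments):
        h_wrap = np.append(profiles[i], profiles[i, 0])
        h_pts = np.interp(x_pts, x_wrap, h_wrap)
        h_det = h_pts - (h_pts[0] + (h_pts[-1] - h_pts[0]) * x_pts / L)
        clean = np.column_stack([x_pts, h_pts])
        seg_len = float(np.sum(np.linalg.norm(np.diff(clean, axis=0), axis=1)))
        chord = float(np.linalg.norm(clean[-1] - clean[0]))

        theta = rng.uniform(-spec.rotation_range, spec.rotation_range)
        c, s = np.cos(theta), np.sin(theta)
        shift = rng.uniform(0.0, 100.0, size=2)
        pts = clean @ np.array([[c, s], [-s, c]]) + shift
        has_overhang = i in over_idx
        if has_overhang:
            pts = _insert_loop(pts, rng, radius=1.5 * spec.point_spacing_um)
        if spec.jitter_sd > 0:
            pts = pts + rng.normal(0.0, spec.jitter_sd, pts.shape)

        polylines.append(Polyline(segment_id=i, points=pts))
        rows.append({
            "segment_id": i,
            "model": spec.model,
            "chord_length_um": chord,
            "has_overhang": has_overhang,
            "true_tortuosity": seg_len / chord,
            "true_amplitude_um": float(np.max(np.abs(h_det))),
        })
    return polylines, pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# profile time series
# --------------------------------------------------------------------------- #

def make_profile_series(
    dh: float,
    D: float,
    grid: sim.Grid1D,
    delta_t: float,
    n_timepoints: int = 4,
    n_series: int = 50,
    seed: int = 0,
    n_substeps: int = 1,
) -> tuple[list[ProfileSeries], dict]:
    """Edwards-Wilkinson boundary series with known d_h, sampled every
    ``delta_t`` (a few frames per segment, as in live-imaging experiments).

    With noise, each series starts from an independent stationary state;
    frames advance by ``n_substeps`` explicit-Euler steps of size
    delta_t/n_substeps (1 substep realizes the discrete-time lattice model at
    the frame interval; more substeps emulate coarse temporal sampling of
    faster dynamics). With D=0 each series deterministically relaxes from a
    unit sine.
    """
    if n_timepoints < 2 or n_series < 1:
        raise ParameterError("need >= 2 timepoints and >= 1 series")
    if n_substeps < 1:
        raise ParameterError("n_substeps must be >= 1")
    dt = delta_t / n_substeps
    params = sim.EWParams(dh=dh, noise=sim.NoiseSpec(D=D, seed=seed))
    if dt > sim.ew_stable_dt(grid, dh) * (1 + 1e-12):
        raise sim.StabilityError(
            f"delta_t/n_substeps={dt} violates the stability bound "
            f"dx^2/(2*dh)={sim.ew_stable_dt(grid, dh):.6g}"
        )
    rng = np.random.default_rng(seed)
    times = np.arange(n_timepoints) * delta_t

    if D > 0 and dh > 0:
        ics = sim.ew_snapshot_ensemble(grid, params, dt, n_snapshots=n_series, rng=rng)
    else:
        ics = np.tile(np.sin(2.0 * np.pi * grid.x / grid.length), (n_series, 1))

    series: list[ProfileSeries] = []
    for i in range(n_series):
        prof = np.empty((n_timepoints, grid.n_points))
        prof[0] = ics[i]
        state = ics[i]
        for t in range(1, n_timepoints):
            state = sim.simulate_edwards_wilkinson(
                grid, params, n_substeps, dt, record_every=n_substeps,
                h0=state, rng=rng,
            ).final
            prof[t] = state
        series.append(ProfileSeries(times=times, profiles=prof,
                                    dx=grid.dx, segment_id=i))
    truth = {"dh": dh, "D": D, "delta_t": delta_t,
             "n_timepoints": n_timepoints, "n_series": n_series,
             "n_substeps": n_substeps, "seed": seed}
    return series, truth


# --------------------------------------------------------------------------- #
# kymographs and puncta scenes
# --------------------------------------------------------------------------- #

def make_kymograph(spec: PunctaSceneSpec) -> tuple[Kymograph, dict]:
    """Render a line of Gaussian puncta over time as a kymograph.

    Puncta live on a periodic line of ``n_pixels * pixel_size_um`` um; each
    frame adds an independent random-walk step of SD ``mobility_sd`` to every
    punctum and optional Gaussian background noise (clipped at zero). Ground
    truth includes the designed smallest-unit size ``spacing_um/2`` for
    periodic placement.
    """
    rng = np.random.default_rng(spec.seed)
    extent = spec.extent_um
    if spec.spacing_um is not None:
        centers = (np.arange(spec.n_puncta) + 0.5) * spec.spacing_um % extent
    else:
        centers = rng.uniform(0.0, extent, spec.n_puncta)
    xs = (np.arange(spec.n_pixels) + 0.5) * spec.pixel_size_um
    frames = np.zeros((spec.n_pixels, spec.n_frames))
    sigma2 = spec.radius_um**2
    for t in range(spec.n_frames):
        if t > 0 and spec.mobility_sd > 0 and spec.n_puncta:
            centers = (centers + rng.normal(0.0, spec.mobility_sd, centers.shape)) % extent
        if spec.n_puncta:
            d = xs[:, None] - centers[None, :]
            d -= extent * np.round(d / extent)  # periodic minimum-image distance
            frames[:, t] = spec.intensity * np.exp(-d * d / (2.0 * sigma2)).sum(axis=1)
    if spec.background_sd > 0:
        frames = frames + rng.normal(0.0, spec.background_sd, frames.shape)
    frames = np.clip(frames, 0.0, None)
    truth = {
        "n_puncta": spec.n_puncta,
        "radius_um": spec.radius_um,
        "spacing_um": spec.spacing_um,
        "unit_size_um": None if spec.spacing_um is None else spec.spacing_um / 2.0,
        "mobility_sd": spec.mobility_sd,
        "seed": spec.seed,
    }
    return Kymograph(frames, spec.pixel_size_um, spec.frame_interval), truth


def make_puncta_image(
    n_puncta: int,
    radius_um: float = 0.3,
    intensity: float = 1.0,
    background_sd: float = 0.0,
    shape_px: tuple[int, int] = (128, 128),
    pixel_size_um: float = 0.1541,
    min_separation_um: Optional[float] = None,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """2-D scene of Gaussian puncta for threshold counting, with centers
    rejection-sampled to a minimum separation (default 6x radius) so each
    punctum is a distinct connected component at half-maximum threshold."""
    if n_puncta < 0:
        raise ParameterError("n_puncta must be >= 0")
    if not radius_um > 0:
        raise ParameterError("radius_um must be positive")
    rng = np.random.default_rng(seed)
    ny, nx = shape_px
    ext_y, ext_x = ny * pixel_size_um, nx * pixel_size_um
    sep = 6.0 * radius_um if min_separation_um is None else min_separation_um
    margin = 3.0 * radius_um
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n_puncta:
        cand = rng.uniform([margin, margin], [ext_x - margin, ext_y - margin])
        if all(np.linalg.norm(cand - c) >= sep for c in centers):
            centers.append(cand)
        attempts += 1
        if attempts > 10000 * max(1, n_puncta):
            raise ParameterError("could not place puncta at the requested separation")
    img = np.zeros((ny, nx))
    xs = (np.arange(nx) + 0.5) * pixel_size_um
    ys = (np.arange(ny) + 0.5) * pixel_size_um
    for cx, cy in centers:
        img += intensity * np.exp(
            -((xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2) / (2.0 * radius_um**2)
        )
    if background_sd > 0:
        img = img + rng.normal(0.0, background_sd, img.shape)
    img = np.clip(img, 0.0, None)
    truth = pd.DataFrame(
        [{"x_um": c[0], "y_um": c[1]} for c in centers]
    )
    return img, truth
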