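"""Unit and oracle tests for the boundary-dynamics simulators."""

import numpy as np
import pytest

from interdigit import boundary_quant as bq
from interdigit import simulators as sim
from interdigit.errors import ConfigurationError, ParameterError, StabilityError


@pytest.fixture
def grid():
    return sim.Grid1D(256, 1.0)


# --------------------------------------------------------------------------- #
# white noise
# --------------------------------------------------------------------------- #

class TestWhiteNoise:
    def test_zero_noise_stays_flat(self, grid):
        traj = sim.simulate_white_noise(grid, sim.NoiseSpec(D=0.0), 100, 0.01)
        assert np.all(traj.profiles == 0.0)

    def test_per_site_variance_matches_iid_increment_sum(self, grid):
        # var(h(T)) = D*T/dx: sum of n_steps i.i.d. Normal(0, D*dt/dx)
        D, dt, steps = 1.0, 0.01, 10_000
        finals = [
            sim.simulate_white_noise(grid, sim.NoiseSpec(D=D, seed=s), steps, dt,
                                     record_every=steps).final
            for s in range(8)
        ]
        var = np.concatenate(finals).var()
        assert var == pytest.approx(D * steps * dt / grid.dx, rel=0.10)

    def test_ensemble_spectrum_is_flat(self, grid):
        # independent runs -> flat log-log ensemble spectrum
        finals = np.stack([
            sim.simulate_white_noise(grid, sim.NoiseSpec(D=1.0, seed=s), 500, 0.01,
                                     record_every=500).final
            for s in range(100)
        ])
        fit = bq.fit_scaling(bq.ensemble_periodic_spectrum(finals), 2, 32)
        assert abs(fit.exponent) < 0.1

    @pytest.mark.parametrize("dt,steps", [(0.0, 10), (-1.0, 10), (0.1, 0)])
    def test_invalid_step_parameters(self, grid, dt, steps):
        with pytest.raises(ParameterError):
            sim.simulate_white_noise(grid, sim.NoiseSpec(), steps, dt)


# --------------------------------------------------------------------------- #
# Edwards-Wilkinson
# --------------------------------------------------------------------------- #

class TestEdwardsWilkinson:
    def test_single_mode_decay_matches_closed_form(self, grid):
        # noiseless EW relaxes a sine at exp(-dh*lambda_1*t)
        params = sim.EWParams(dh=1.0, noise=sim.NoiseSpec(D=0.0))
        dt = grid.dx**2 / 20.0
        steps = 4000
        h0 = np.sin(2 * np.pi * grid.x / grid.length)
        traj = sim.simulate_edwards_wilkinson(grid, params, steps, dt,
                                              record_every=steps, h0=h0)
        # project onto the initial mode
        amp = 2.0 * np.abs(np.vdot(h0, traj.final)) / grid.n_points
        lam1 = grid.laplacian_eigenvalue(1)
        expected = np.exp(-params.dh * lam1 * steps * dt)
        assert amp == pytest.approx(expected, rel=0.005)

    def test_stability_violation_raises_named_bound(self, grid):
        params = sim.EWParams(dh=4.0)
        with pytest.raises(StabilityError, match="dx\\^2/\\(2\\*dh\\)"):
            sim.simulate_edwards_wilkinson(grid, params, 10, 0.2)

    def test_stationary_mode_variance_matches_ou_oracle(self):
        # per-mode discrete Ornstein-Uhlenbeck stationary variance,
        # exact for the Euler chain: E|H_k|^2 = N*sigma^2/(a*(2-a))
        grid = sim.Grid1D(64, 1.0)
        params = sim.EWParams(dh=1.0, noise=sim.NoiseSpec(D=1.0, seed=11))
        dt = 0.1
        snaps = sim.ew_snapshot_ensemble(grid, params, dt, n_snapshots=400,
                                         spacing_mode=4)
        measured = bq.ensemble_periodic_spectrum(snaps)
        ks = np.arange(4, 28)
        predicted = sim.ew_stationary_mode_power(grid, params, dt, ks)
        ratio = measured.power[ks - 1] / predicted
        # per-mode Monte Carlo error with ~400 effective samples
        assert np.all(np.abs(ratio - 1.0) < 0.35)
        assert np.mean(ratio) == pytest.approx(1.0, abs=0.05)

    def test_stationary_spectrum_slope_minus_two(self, grid):
        params = sim.EWParams(dh=1.0, noise=sim.NoiseSpec(D=1.0, seed=1))
        snaps = sim.ew_snapshot_ensemble(grid, params, dt=0.05, n_snapshots=100)
        fit = bq.fit_scaling(bq.ensemble_periodic_spectrum(snaps), 2, 32)
        assert fit.exponent == pytest.approx(-2.0, abs=0.1)

    def test_ensemble_spatial_mean_is_conserved(self):
        # Laplacian and zero-mean noise preserve the expected spatial mean
        grid = sim.Grid1D(64, 1.0)
        params = sim.EWParams(dh=1.0, noise=sim.NoiseSpec(D=1.0, seed=7))
        rng = np.random.default_rng(7)
        means = [
            sim.simulate_edwards_wilkinson(grid, params, 2000, 0.1,
                                           record_every=2000, rng=rng).final.mean()
            for _ in range(100)
        ]
        # mean of spatial means ~ N(0, D*T/(N*dx)/n_runs)
        se = np.sqrt(1.0 * 2000 * 0.1 / (64 * 1.0)) / np.sqrt(100)
        assert abs(np.mean(means)) < 3 * se


# --------------------------------------------------------------------------- #
# Turing
# --------------------------------------------------------------------------- #

class TestTuring:
    def test_exact_steady_state_stays_uniform(self):
        grid = sim.Grid1D(64, 1.0)
        params = sim.TuringParams(du=1.0, dv=40.0, perturbation_sd=0.0)
        us, vs = params.kinetics.steady_state()
        traj = sim.simulate_turing(grid, params, 200, 0.01)
        assert np.allclose(traj.profiles, us, atol=1e-12)
        assert np.allclose(traj.aux_profiles, vs, atol=1e-12)

    def test_spectral_peak_at_most_unstable_mode(self):
        grid = sim.Grid1D(128, 1.0)
        params = sim.TuringParams(du=1.0, dv=40.0, seed=3)
        dt = 0.5 * sim.turing_stable_dt(grid, params)
        steps = int(20.0 / dt)
        traj = sim.simulate_turing(grid, params, steps, dt, record_every=steps)
        spec = bq.periodic_power_spectrum(traj.final)
        k_peak = int(spec.k[np.argmax(spec.power)])
        k_pred = sim.most_unstable_mode(sim.turing_dispersion(grid, params))
        assert abs(k_peak - k_pred) <= 1

    def test_stable_kinetics_decay(self):
        # equal diffusion cannot destabilize Schnakenberg kinetics; the
        # perturbation's total power decays (sampled every ~10 time units to
        # ride over the damped oscillation of the complex eigenpair)
        grid = sim.Grid1D(64, 1.0)
        params = sim.TuringParams(du=1.0, dv=1.0, perturbation_sd=1e-3, seed=5)
        assert not params.is_turing_unstable
        dt = 0.25 * sim.turing_stable_dt(grid, params)
        steps_per_block = int(10.0 / dt)
        us, _ = params.kinetics.steady_state()
        with pytest.warns(UserWarning):
            traj = sim.simulate_turing(grid, params, 4 * steps_per_block, dt,
                                       record_every=steps_per_block,
                                       allow_stable=True)
        power = np.sum((traj.profiles - us) ** 2, axis=1)
        assert np.all(np.diff(power) < 0)
        assert power[-1] < 1e-2 * power[0]

    def test_stable_parameters_rejected_by_default(self):
        grid = sim.Grid1D(64, 1.0)
        params = sim.TuringParams(du=1.0, dv=1.0)
        with pytest.raises(ConfigurationError):
            sim.simulate_turing(grid, params, 10, 0.01)


# --------------------------------------------------------------------------- #
# buckling
# --------------------------------------------------------------------------- #

class TestBuckling:
    def test_pure_hyperdiffusion_decays_monotonically(self):
        grid = sim.Grid1D(64, 1.0)
        params = sim.BucklingParams(c=0.0, d=1.0)
        h0 = np.sin(2 * np.pi * 3 * grid.x / grid.length)
        dt = 0.5 * sim.buckling_stable_dt(grid, params)
        traj = sim.simulate_buckling(grid, params, 500, dt, record_every=50, h0=h0)
        amps = np.max(np.abs(traj.profiles), axis=1)
        assert np.all(np.diff(amps) < 0)

    def test_fastest_mode_growth_rate_quarter(self):
        # c=d=1: lambda(k*) = c^2/(4d) = 0.25 at k* = 1/sqrt(2) rad/um;
        # pick L so that k* falls exactly on integer mode 4
        m, c, d = 4, 1.0, 1.0
        L = 2 * np.pi * m * np.sqrt(2.0)
        grid = sim.Grid1D(128, L / 128)
        params = sim.BucklingParams(c=c, d=d)
        dt = 0.5 * sim.buckling_stable_dt(grid, params)
        steps = int(20.0 / dt)
        h0 = 1e-3 * np.sin(2 * np.pi * m * grid.x / L)
        traj = sim.simulate_buckling(grid, params, steps, dt,
                                     record_every=steps, h0=h0)
        growth = np.max(np.abs(traj.final)) / 1e-3
        assert growth == pytest.approx(np.exp(0.25 * steps * dt), rel=0.01)

    def test_spectral_peak_near_kstar(self):
        grid = sim.Grid1D(256, 0.5)
        params = sim.BucklingParams(c=1.0, d=1.0)
        dt = 0.5 * sim.buckling_stable_dt(grid, params)
        steps = int(40.0 / dt)
        traj = sim.simulate_buckling(grid, params, steps, dt, record_every=steps,
                                     seed=4, init_sd=1e-4)
        spec = bq.periodic_power_spectrum(traj.final)
        k_peak = int(spec.k[np.argmax(spec.power)])
        k_pred = sim.most_unstable_mode(sim.buckling_dispersion(grid, params))
        k_star_mode = params.fastest_wavenumber * grid.length / (2 * np.pi)
        assert abs(k_peak - k_pred) <= 1
        assert abs(k_peak - k_star_mode) <= 1.0

    def test_nonpositive_bending_rejected(self):
        with pytest.raises(ParameterError):
            sim.BucklingParams(c=1.0, d=0.0)

    def test_stability_violation(self):
        grid = sim.Grid1D(64, 1.0)
        with pytest.raises(StabilityError):
            sim.simulate_buckling(grid, sim.BucklingParams(c=1.0, d=1.0), 10, 1.0)


# --------------------------------------------------------------------------- #
# cross-model invariants
# --------------------------------------------------------------------------- #

def test_seed_determinism_all_models(grid):
    """Identical (params, seed, grid, dt, n_steps) => bit-identical output."""

    def runs():
        yield lambda: sim.simulate_white_noise(grid, sim.NoiseSpec(D=1.0, seed=9), 50, 0.01)
        yield lambda: sim.simulate_edwards_wilkinson(
            grid, sim.EWParams(dh=1.0, noise=sim.NoiseSpec(D=1.0, seed=9)), 50, 0.05)
        yield lambda: sim.simulate_turing(
            grid, sim.TuringParams(du=1.0, dv=40.0, seed=9), 50, 0.01)
        yield lambda: sim.simulate_buckling(
            grid, sim.BucklingParams(c=1.0, d=1.0), 50,
            0.5 * sim.buckling_stable_dt(grid, sim.BucklingParams(c=1.0, d=1.0)),
            seed=9, init_sd=1e-3)

    for make in runs():
        a, b = make(), make()
        np.testing.assert_array_equal(a.profiles, b.profiles)


def test_snapshot_ensemble_deterministic(grid):
    params = sim.EWParams(dh=1.0, noise=sim.NoiseSpec(D=1.0, seed=2))
    a = sim.ew_snapshot_ensemble(grid, params, 0.05, n_snapshots=3, burn_relax=0.1)
    b = sim.ew_snapshot_ensemble(grid, params, 0.05, n_snapshots=3, burn_relax=0.1)
    np.testing.assert_array_equal(a, b)


def test_pattern_spectra_are_peaked_not_power_law():
    """Turing and buckling end-of-growth spectra: peak power exceeds the power
    at twice the peak wavenumber by more than 5x."""
    grid = sim.Grid1D(128, 1.0)
    tp = sim.TuringParams(du=1.0, dv=40.0, seed=3)
    dt = 0.5 * sim.turing_stable_dt(grid, tp)
    steps = int(20.0 / dt)
    traj = sim.simulate_turing(grid, tp, steps, dt, record_every=steps)
    spec = bq.periodic_power_spectrum(traj.final)

    gb = sim.Grid1D(256, 0.5)
    bp = sim.BucklingParams(c=1.0, d=1.0)
    dtb = 0.5 * sim.buckling_stable_dt(gb, bp)
    stepsb = int(40.0 / dtb)
    trajb = sim.simulate_buckling(gb, bp, stepsb, dtb, record_every=stepsb,
                                  seed=4, init_sd=1e-4)
    specb = bq.periodic_power_spectrum(trajb.final)

    for s in (spec, specb):
        k_peak = int(s.k[np.argmax(s.power)])
        assert s.power[k_peak - 1] / s.power[2 * k_peak - 1] > 5.0
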