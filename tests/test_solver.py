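import numpy as np
import pytest
from scipy.signal import butter, correlate, filtfilt, find_peaks, hilbert

from echodome.geometry import VoxelGrid
from echodome.solver import (
    ConfigurationError,
    SimulationConfig,
    StabilityError,
    apply_pml_coefficients,
    compute_time_step,
    floor_boundary,
    run_simulation,
)

NO_FLOOR = dict(floor_thickness=0.0, floor_reflection=1.0)


def gauss_burst(dt, f0, sig_cycles=3.0):
    """Zero-mean Gaussian-windowed tone burst (no DC)."""
    sig_t = sig_cycles / f0
    t = np.arange(int(8 * sig_t / dt)) * dt
    return np.exp(-((t - 4 * sig_t) ** 2) / (2 * sig_t**2)) * np.sin(
        2 * np.pi * f0 * (t - 4 * sig_t)
    )


class TestTimeStep:
    @pytest.mark.parametrize(
        "dx, expected",
        [(0.2, 2.9412e-7), (1.0, 1.47059e-6)],
    )
    def test_dt_follows_cfl_rule(self, dx, expected):
        cfg = SimulationConfig(dx=dx, cfl=0.5, c=340.0)
        assert compute_time_step(cfg) == pytest.approx(expected, rel=1e-4)

    def test_courant_number_above_3d_bound_rejected(self):
        with pytest.raises(StabilityError, match="1/sqrt"):
            SimulationConfig(cfl=0.6)

    def test_dx_must_divide_domain(self):
        with pytest.raises(ConfigurationError, match="divide"):
            SimulationConfig(domain_size=(421.0, 220.0, 80.0), dx=2.0)


class TestPMLCoefficients:
    def test_profile_is_zero_in_interior_and_max_at_edge(self):
        cfg = SimulationConfig(dx=2.0, pml_max_damping=5e4)
        pml = apply_pml_coefficients(cfg)
        n = cfg.pml_cells
        assert np.all(pml.sigma_x[n:-n] == 0.0)
        assert pml.sigma_x[0] == pytest.approx(5e4)
        assert pml.sigma_x[-1] == pytest.approx(5e4)
        assert pml.sigma_z[0] == 0.0  # floor face has no PML by default

    def test_too_few_pml_cells_rejected(self):
        with pytest.raises(ConfigurationError, match="pml_cells"):
            SimulationConfig(pml_cells=2)

    def test_pml_thicker_than_half_domain_rejected(self):
        with pytest.raises(ConfigurationError, match="pml_cells"):
            SimulationConfig(
                domain_size=(30.0, 220.0, 80.0), dx=1.0, pml_cells=15,
                source_position=(15.0, 110.0, 24.0), receiver_position=(15.0, 110.0, 27.0),
            )

    def test_normal_incidence_reflection_below_minus_40db(self):
        """Quasi-1D tube onto the x+ PML; reflection isolated by
        subtracting a longer-domain reference run."""
        base = dict(
            dx=2.0, duration_ms=2.8, pml_faces=("x+",),
            source_position=(60.0, 8.0, 8.0), receiver_position=(200.0, 8.0, 8.0),
            **NO_FLOOR,
        )
        cfg = SimulationConfig(domain_size=(300.0, 16.0, 16.0), **base)
        cfg_ref = SimulationConfig(domain_size=(1200.0, 16.0, 16.0), **base)
        w = gauss_burst(cfg.dt, 40e3)
        tr = run_simulation(cfg, source=w)
        tr_ref = run_simulation(cfg_ref, source=w)
        n = len(tr.samples)
        reflected = tr.samples.astype(float) - tr_ref.samples.astype(float)[:n]
        incident = np.abs(hilbert(tr_ref.samples.astype(float)[:n])).max()
        ratio = np.abs(hilbert(reflected)).max() / incident
        assert 20 * np.log10(ratio) < -40.0


class TestFloorBoundary:
    def _reflection(self, R):
        cfg = SimulationConfig(
            domain_size=(16.0, 16.0, 300.0), dx=2.0, duration_ms=2.2,
            floor_thickness=10.0, floor_reflection=R, pml_faces=("z+",),
            source_position=(8.0, 8.0, 210.0), receiver_position=(8.0, 8.0, 150.0),
        )
        tr = run_simulation(cfg, source=gauss_burst(cfg.dt, 5e3, sig_cycles=1.5))
        env = np.abs(hilbert(tr.samples.astype(float)))
        peaks, _ = find_peaks(env, height=1e-4 * env.max(), distance=80)
        incident = env[peaks[0]]
        reflected = env[peaks[1]] if len(peaks) > 1 else 0.0
        return incident, reflected

    def test_r099_amplitude_ratio_in_band(self):
        _, rigid = self._reflection(1.0)
        _, soft = self._reflection(0.99)
        assert 0.97 <= soft / rigid <= 1.0

    def test_r1_limit_is_rigid(self):
        fb = floor_boundary(SimulationConfig(floor_reflection=1.0))
        assert np.isinf(fb.zeta) and fb.ghost_coefficient == 0.0

    def test_r0_floor_echo_strongly_absorbed(self):
        """A locally reacting first-order impedance ghost leaves an O(dx)
        residual at broadband incidence; R = 0 suppresses the floor echo by
        more than 12 dB (the boundary's documented accuracy limit)."""
        _, rigid = self._reflection(1.0)
        _, absorbed = self._reflection(0.0)
        assert absorbed / rigid < 0.25

    def test_invalid_reflection_rejected(self):
        with pytest.raises(ConfigurationError, match="floor_reflection"):
            SimulationConfig(floor_reflection=1.5)


class TestPropagation:
    @pytest.mark.parametrize("distance", [60.0, 100.0, 140.0])
    def test_free_field_arrival_at_d_over_c(self, distance):
        """Band-limited matched-filter arrival within +-2 dt of d/c."""
        cfg = SimulationConfig(
            domain_size=(240.0, 60.0, 60.0), dx=2.0, duration_ms=1.0,
            pml_faces=("x-", "x+", "y-", "y+", "z-", "z+"),
            source_position=(40.0, 30.0, 30.0),
            receiver_position=(40.0 + distance, 30.0, 30.0),
            **NO_FLOOR,
        )
        tr = run_simulation(cfg)
        t = _matched_arrival(tr.samples, tr.dt, f_max=12e3)
        assert t == pytest.approx(distance * 1e-3 / 340.0, abs=2 * cfg.dt)

    def test_free_field_error_decreases_with_dx(self):
        """Grid refinement at a fixed physical setup (including constant
        20 mm PML thickness): the arrival-time error shrinks monotonically
        as dx is halved."""
        errs = []
        for dx in (2.0, 1.0, 0.5):
            cfg = SimulationConfig(
                domain_size=(160.0, 48.0, 48.0), dx=dx, duration_ms=0.55,
                pml_faces=("x-", "x+", "y-", "y+", "z-", "z+"),
                pml_cells=int(round(20.0 / dx)),
                source_position=(20.0, 24.0, 24.0),
                receiver_position=(120.0, 24.0, 24.0),
                **NO_FLOOR,
            )
            tr = run_simulation(cfg)
            t = _matched_arrival(tr.samples, tr.dt, f_max=17e3)
            errs.append(abs(t - 100e-3 / 340.0))
        assert errs[0] >= errs[1] >= errs[2]

    def test_plane_reflector_echo_at_two_d_over_c(self):
        d = 120.0
        cfg = SimulationConfig(
            domain_size=(300.0, 120.0, 120.0), dx=2.0, duration_ms=1.3,
            pml_faces=("x-", "x+", "y-", "y+", "z-", "z+"),
            source_position=(160.0 + d, 60.0, 60.0),
            receiver_position=(160.0 + d - 6.0, 60.0, 60.0),
            **NO_FLOOR,
        )
        occ = np.zeros(cfg.grid_shape, bool)
        occ[76:80, :, :] = True  # rigid slab, reflecting face at x = 160 mm
        slab = VoxelGrid(occ, 2.0, origin=np.zeros(3))
        free = run_simulation(cfg).samples.astype(float)
        total = run_simulation(cfg, obstacles=slab).samples.astype(float)
        t = _matched_arrival(total - free, cfg.dt, f_max=12e3)
        expected = (d + (d - 6.0)) * 1e-3 / 340.0
        assert t == pytest.approx(expected, abs=2 * cfg.dt)

    def test_no_source_yields_silence(self):
        cfg = SimulationConfig(
            domain_size=(60.0, 60.0, 60.0), dx=2.0, duration_ms=0.3,
            source_position=(30.0, 30.0, 30.0), receiver_position=(40.0, 30.0, 30.0),
        )
        tr = run_simulation(cfg, source=None)
        assert np.all(tr.samples == 0.0)

    def test_trace_length_contract(self):
        cfg = SimulationConfig(domain_size=(120.0, 120.0, 60.0), dx=2.0, duration_ms=2.65,
                               source_position=(60.0, 60.0, 30.0),
                               receiver_position=(70.0, 60.0, 32.0))
        tr = run_simulation(cfg, source=None)
        assert len(tr.samples) == int(np.floor(2.65e-3 / tr.dt)) + 1


class TestConservation:
    def test_energy_bounded_and_conserved_in_rigid_box(self):
        """10 000 steps at chi = 0.5 in a closed rigid box: the discrete
        leapfrog energy stays constant after the source stops."""
        cfg = SimulationConfig(
            domain_size=(80.0, 80.0, 80.0), dx=2.0, duration_ms=30.0,
            pml_faces=(), precision="float64",
            source_position=(40.0, 40.0, 40.0), receiver_position=(60.0, 40.0, 40.0),
            **NO_FLOOR,
        )
        assert cfg.n_steps >= 10_000
        tr = run_simulation(cfg, source=gauss_burst(cfg.dt, 10e3), energy_interval=500)
        assert np.isfinite(tr.samples).all()
        after_source = tr.energies[1:]
        drift = (after_source.max() - after_source.min()) / after_source.mean()
        assert drift < 0.01

    def test_reciprocity(self):
        """Swapping source and receiver in a homogeneous rigid box yields
        the identical trace."""
        a = (30.0, 20.0, 30.0)
        b = (90.0, 60.0, 40.0)
        kwargs = dict(
            domain_size=(120.0, 80.0, 60.0), dx=2.0, duration_ms=1.0,
            pml_faces=(), precision="float64", **NO_FLOOR,
        )
        tr_ab = run_simulation(
            SimulationConfig(source_position=a, receiver_position=b, **kwargs)
        )
        tr_ba = run_simulation(
            SimulationConfig(source_position=b, receiver_position=a, **kwargs)
        )
        err = np.abs(tr_ab.samples - tr_ba.samples).max()
        assert err <= 1e-6 * np.abs(tr_ab.samples).max()


class TestConfigurationGuards:
    def test_source_inside_pml_rejected(self):
        with pytest.raises(ConfigurationError, match="PML"):
            SimulationConfig(source_position=(5.0, 110.0, 24.0))

    def test_source_inside_floor_rejected(self):
        with pytest.raises(ConfigurationError, match="floor"):
            SimulationConfig(source_position=(380.0, 110.0, 5.0))

    def test_obstacle_overlapping_source_rejected(self):
        cfg = SimulationConfig(
            domain_size=(60.0, 60.0, 60.0), dx=2.0, duration_ms=0.2,
            source_position=(30.0, 30.0, 30.0), receiver_position=(40.0, 30.0, 30.0),
        )
        occ = np.zeros(cfg.grid_shape, bool)
        occ[13:17, 13:17, 13:17] = True  # covers the source cell
        with pytest.raises(ConfigurationError, match="overlaps"):
            run_simulation(cfg, obstacles=VoxelGrid(occ, 2.0, origin=np.zeros(3)))

    def test_obstacle_dx_mismatch_rejected(self):
        cfg = SimulationConfig(
            domain_size=(60.0, 60.0, 60.0), dx=2.0, duration_ms=0.2,
            source_position=(30.0, 30.0, 30.0), receiver_position=(40.0, 30.0, 30.0),
        )
        occ = np.zeros((10, 10, 10), bool)
        occ[5, 5, 5] = True
        with pytest.raises(ConfigurationError, match="dx"):
            run_simulation(cfg, obstacles=VoxelGrid(occ, 1.0, origin=np.zeros(3)))


def _matched_arrival(samples, dt, f_max):
    """Arrival time via lowpass + matched doublet + envelope peak."""
    x = np.concatenate([np.asarray(samples, float), np.zeros(int(4 / (f_max * dt)))])
    b, a = butter(4, f_max / (0.5 / dt), btype="low")
    xf = filtfilt(b, a, x)[: len(samples)]
    m = len(xf) | 1
    dd = np.zeros(m)
    dd[m // 2] = 1.0
    dd[m // 2 + 1] = -1.0
    w = filtfilt(b, a, dd)
    env = np.abs(hilbert(correlate(xf, w, mode="same")))
    i = int(np.argmax(env))
    frac = 0.0
    if 0 < i < len(env) - 1:  # parabolic sub-sample refinement
        a, b, c = env[i - 1], env[i], env[i + 1]
        denom = a - 2 * b + c
        if denom != 0:
            frac = 0.5 * (a - c) / denom
    return (i + frac + 0.5 - 1) * dt
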