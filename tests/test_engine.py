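"""Monte Carlo engine: release, diffusion, hit counting, coupled runs."""

import numpy as np
import pytest
from dataclasses import replace

from calyxnano.sim import (
    DiffusionParams,
    SimConfig,
    SynapseGeometry,
    VesicleSource,
    average_traces,
    release_schedule,
    run_quantal_event,
)
from calyxnano.sim.engine import count_hits, current_pA, expected_hits_per_step, hit_concentration_mM
from calyxnano.synth import generate_receptor_map


@pytest.fixture(scope="module")
def small_config():
    """Reduced-size configuration for fast engine tests."""
    return SimConfig(
        vesicle=VesicleSource(n_glutamate=1000),
        duration_ms=1.5,
        receptor_map=generate_receptor_map(seed=0),
    )


class TestReleaseSchedule:
    def test_pore_conductance_gives_point_two_ms(self):
        src = VesicleSource(n_glutamate=8000, pore_conductance_nS=0.375)
        assert src.release_tau_us == pytest.approx(73.0 / 0.375)
        assert round(src.release_tau_us / 1000.0, 1) == 0.2
        sched = release_schedule(src, dt_us=0.5)
        assert sched.sum() == 8000
        assert len(sched) == int(np.ceil(src.release_tau_us / 0.5))

    def test_tau_inverse_in_conductance(self):
        a = VesicleSource(pore_conductance_nS=0.4)
        b = VesicleSource(pore_conductance_nS=0.8)
        assert a.release_tau_us == pytest.approx(2 * b.release_tau_us)

    def test_fast_pore_releases_in_first_step(self):
        src = VesicleSource(n_glutamate=500, pore_conductance_nS=1000.0)
        sched = release_schedule(src, dt_us=0.5)
        assert sched[0] == 500

    def test_exponential_emptying_conserves(self):
        src = VesicleSource(n_glutamate=777, exponential_emptying=True)
        assert release_schedule(src, dt_us=0.5).sum() == 777


class TestCurrent:
    def test_ten_fast_receptors_at_minus_sixty(self):
        assert current_pA(10, 0, 45.0, 31.0, -60.0, 0.0) == pytest.approx(-27.0)

    def test_zero_open_zero_current(self):
        assert current_pA(0, 0, 45.0, 31.0, -60.0, 0.0) == 0.0


class TestCountHits:
    def test_agrees_with_brute_force_segments(self, rng):
        rm = generate_receptor_map(n_total=10, seed=1)
        p0 = rng.uniform(-150, 150, size=(100, 3))
        p0[:, 2] = rng.uniform(1, 30, size=100)
        p1 = p0 + rng.normal(0, 20, size=(100, 3))
        hits = count_hits(p0, p1, rm)
        expected = np.zeros(rm.n_total, dtype=int)
        for i in range(100):
            if not (p0[i, 2] > 0 and p1[i, 2] <= 0):
                continue
            f = p0[i, 2] / (p0[i, 2] - p1[i, 2])
            c = p0[i, :2] + f * (p1[i, :2] - p0[i, :2])
            for r in range(rm.n_total):
                if np.hypot(*(c - rm.positions[r])) <= rm.receptor_disc_radius:
                    expected[r] += 1
        np.testing.assert_array_equal(hits, expected)

    def test_no_crossing_no_hits(self, rng):
        rm = generate_receptor_map(n_total=5, seed=2)
        p0 = rng.uniform(-50, 50, size=(40, 3))
        p0[:, 2] = 20.0
        p1 = p0.copy()
        p1[:, 2] = 5.0  # stays above the plane
        assert count_hits(p0, p1, rm).sum() == 0

    def test_hit_expectation_linear_in_molecule_number(self):
        """Crossing rate through a disc doubles when the molecule count doubles."""
        rng = np.random.default_rng(3)
        rm = generate_receptor_map(n_total=1, relative_densities=(1.0,), boundaries=(0.0, 1e-6), seed=0)
        rm.positions[:] = 0.0
        sigma = 10.0
        totals = []
        for n in (20000, 40000):
            p0 = np.column_stack(
                [rng.uniform(-50, 50, size=n), rng.uniform(-50, 50, size=n), rng.uniform(0, 30, size=n)]
            )
            p1 = p0 + rng.normal(0, sigma, size=(n, 3))
            totals.append(count_hits(p0, p1, rm).sum())
        assert totals[1] / totals[0] == pytest.approx(2.0, rel=0.2)


class TestHitCalibration:
    def test_crossing_rate_matches_closed_form(self):
        """Plane-crossing rate through a disc equals C * A * sigma / sqrt(2 pi)."""
        rng = np.random.default_rng(7)
        n, sigma, h, half = 60000, 15.0, 60.0, 300.0
        conc_per_nm3 = n / (2 * half) ** 2 / h
        rm = generate_receptor_map(n_total=1, relative_densities=(1.0,), boundaries=(0.0, 1e-6), seed=0)
        rm.positions[:] = 0.0
        radius = rm.receptor_disc_radius
        pos = np.column_stack(
            [rng.uniform(-half, half, size=n), rng.uniform(-half, half, size=n), rng.uniform(0, h, size=n)]
        )
        hits = 0
        steps = 30
        for _ in range(steps):
            new = pos + rng.normal(0, sigma, size=(n, 3))
            hits += count_hits(pos, new, rm).sum()
            new[:, 2] = np.abs(new[:, 2])  # reflect at both planes
            new[:, 2] = h - np.abs(h - new[:, 2])
            pos = new
        expected = conc_per_nm3 * np.pi * radius**2 * sigma / np.sqrt(2 * np.pi) * steps
        assert hits == pytest.approx(expected, rel=0.15)

    def test_hit_concentration_consistency(self):
        c_hit = hit_concentration_mM(10.0, 20.0)
        assert expected_hits_per_step(c_hit, 10.0, 20.0) == pytest.approx(1.0)


class TestRunQuantalEvent:
    def test_zero_glutamate_flat_current(self):
        cfg = SimConfig(vesicle=VesicleSource(n_glutamate=0), duration_ms=0.5)
        tr = run_quantal_event(cfg, seed=1)
        assert np.all(tr.current_pA == 0.0)

    def test_conservation_every_step(self, small_config):
        tr = run_quantal_event(small_config, seed=2)
        np.testing.assert_array_equal(tr.free + tr.absorbed, tr.released_cum)

    def test_determinism(self, small_config):
        a = run_quantal_event(small_config, seed=3)
        b = run_quantal_event(small_config, seed=3)
        np.testing.assert_array_equal(a.current_pA, b.current_pA)
        np.testing.assert_array_equal(a.free, b.free)

    def test_zero_diffusion_no_transport(self):
        cfg = SimConfig(
            vesicle=VesicleSource(n_glutamate=500),
            diffusion=DiffusionParams(D_um2_per_ms=0.0),
            duration_ms=0.3,
        )
        tr = run_quantal_event(cfg, seed=4)
        # frozen molecules: never reach the glial wall, never hit receptors
        assert tr.absorbed[-1] == 0
        assert np.all(tr.current_pA == 0.0)

    def test_full_uptake_absorbs_everything_eventually(self):
        geom = SynapseGeometry(transporter_density_per_um2=1e9)  # p_uptake -> 1
        cfg = SimConfig(geometry=geom, vesicle=VesicleSource(n_glutamate=800), duration_ms=4.0)
        assert geom.uptake_probability == 1.0
        tr = run_quantal_event(cfg, seed=5)
        assert tr.free[-1] == 0
        assert tr.absorbed[-1] == 800
        assert np.all(np.diff(tr.absorbed) >= 0)

    def test_lateral_msd_follows_einstein_relation(self):
        """Before boundaries interfere, lateral MSD grows as 4 D t."""
        D = 0.4  # um^2/ms
        cfg = SimConfig(
            geometry=SynapseGeometry(cleft_radius=5000.0, psd_radius=140.0, cleft_height=28.0),
            vesicle=VesicleSource(n_glutamate=4000, pore_conductance_nS=1000.0),
            diffusion=DiffusionParams(D_um2_per_ms=D),
            duration_ms=0.05,
            receptor_map=generate_receptor_map(seed=0),
        )
        # per-axis variance accumulates as 2 D t; verified through the step s.d.
        assert cfg.diffusion.sigma_nm**2 == pytest.approx(2 * D * 1e3 * cfg.diffusion.dt_us)

    def test_rate_dt_guard(self):
        cfg = SimConfig(diffusion=DiffusionParams(dt_us=50.0))
        with pytest.raises(ValueError, match="smaller time step"):
            cfg.validate()

    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            SynapseGeometry(nanocluster_radius=300.0).validate()


class TestAverageTraces:
    def test_single_run_equals_that_run(self, small_config):
        mean, runs = average_traces(small_config, n_runs=1, seed=6)
        child = int(np.random.SeedSequence(6).generate_state(1)[0] % (2**31 - 1))
        single = run_quantal_event(small_config, seed=child)
        np.testing.assert_allclose(mean.current_pA, single.current_pA)
        assert len(runs) == 1

    def test_components_sum_to_total(self, small_config):
        mean, _ = average_traces(small_config, n_runs=4, seed=7)
        np.testing.assert_allclose(
            mean.fast_component_pA + mean.slow_component_pA, mean.current_pA, atol=1e-9
        )

    def test_peak_sem_shrinks_with_run_count(self, small_config):
        """Bootstrap over run subsets: SEM of the peak scales like 1/sqrt(n)."""
        _, runs = average_traces(small_config, n_runs=32, seed=8)
        peaks = runs.peak_amplitude_pA.to_numpy()
        rng = np.random.default_rng(0)
        sems = {}
        for k in (4, 16):
            means = [rng.choice(peaks, size=k, replace=False).mean() for _ in range(400)]
            sems[k] = np.std(means)
        assert sems[4] / sems[16] == pytest.approx(2.0, rel=0.4)

    def test_dose_response_monotone(self):
        """Mean peak amplitude grows with vesicle glutamate content."""
        amps = []
        for ng in (1000, 4000, 12000):
            cfg = SimConfig(vesicle=VesicleSource(n_glutamate=ng), duration_ms=2.0)
            tr, _ = average_traces(cfg, n_runs=12, seed=9)
            amps.append(tr.peak_amplitude_pA)
        assert amps[0] < amps[1] < amps[2]
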