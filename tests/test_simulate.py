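"""Brownian-dynamics simulator: propagator, barrier, photons, oracles."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

import pcfscan as p
from pcfscan.errors import InfeasibleTargetError, ValidationError


def tiny_config(**kw):
    defaults = dict(n_lines=400, n_particles=20, burn_in_s=0.05, seed=42)
    defaults.update(kw)
    return p.paper_scan_config(**defaults)


class TestConfigValidation:
    def test_probability_bounds(self):
        with pytest.raises(ValidationError):
            tiny_config(p_cross=1.5)

    def test_box_guard_against_wall_artifacts(self):
        with pytest.raises(ValidationError):
            tiny_config(box_ly_um=1.0)  # < 6 w0

    def test_active_requires_barrier(self):
        with pytest.raises(ValidationError):
            tiny_config(active=p.ActiveTransport(enabled=True))

    def test_one_sided_init_requires_barrier(self):
        with pytest.raises(ValidationError):
            tiny_config(init="left")

    def test_scan_dead_time(self):
        with pytest.raises(ValidationError):
            p.ScanGeometry(n_pixels=32, pixel_dwell_s=6.3e-6, line_period_s=1e-4)

    def test_paper_scan_preset_geometry(self):
        cfg = p.paper_scan_config()
        assert cfg.scan.n_pixels == 32
        assert cfg.scan.pixel_dwell_s == pytest.approx(6.3e-6)
        assert cfg.scan.line_period_s == pytest.approx(4.73e-4)
        assert cfg.scan.pixel_size_um == pytest.approx(0.1)
        # about one molecule per focal volume
        conc = cfg.n_particles / cfg.volume_um3
        assert conc * cfg.psf.focal_volume_um3 == pytest.approx(1.0, rel=0.05)


class TestSimulation:
    def test_dark_sample_gives_zero_carpet(self):
        res = p.simulate_carpet(tiny_config(brightness=0.0, background=0.0))
        assert res.carpet.counts.sum() == 0

    def test_bit_reproducible_given_seed(self):
        a = p.simulate_carpet(tiny_config(seed=5))
        b = p.simulate_carpet(tiny_config(seed=5))
        np.testing.assert_array_equal(a.carpet.counts, b.carpet.counts)
        c = p.simulate_carpet(tiny_config(seed=6))
        assert not np.array_equal(a.carpet.counts, c.carpet.counts)

    def test_impenetrable_barrier_no_events(self):
        cfg = tiny_config(barrier_x_um=1.55, p_cross=0.0, init="left", n_lines=2000)
        res = p.simulate_carpet(cfg)
        assert len(res.events) == 0
        assert (res.occupancy["right"] == 0).all()

    def test_particle_number_conserved(self):
        cfg = tiny_config(
            barrier_x_um=1.55,
            p_cross=0.1,
            n_lines=2000,
            active=p.ActiveTransport(enabled=True, p_active=0.5,
                                     translocation_mean_s=0.005),
        )
        res = p.simulate_carpet(cfg)
        totals = res.occupancy.sum(axis=1)
        assert (totals == cfg.n_particles).all()

    def test_event_directions_consistent_with_positions(self):
        cfg = tiny_config(barrier_x_um=1.55, p_cross=0.3, n_lines=3000)
        res = p.simulate_carpet(cfg)
        assert len(res.events) > 0
        assert set(res.events["direction"]) <= {-1, 1}
        # net crossings equal the occupancy change between ends of the record
        net = int(res.events["direction"].sum())
        dr = int(res.occupancy["right"].iloc[-1] - res.occupancy["right"].iloc[0])
        assert abs(net - dr) <= 2  # crossings during the first/last line

    def test_detailed_balance_of_passive_crossings(self):
        cfg = tiny_config(barrier_x_um=1.55, p_cross=0.3, n_lines=6000,
                          n_particles=60, burn_in_s=0.5)
        res = p.simulate_carpet(cfg)
        n_r = int((res.events["direction"] == 1).sum())
        n_l = int((res.events["direction"] == -1).sum())
        n = n_r + n_l
        assert n > 200
        assert abs(n_r - n_l) < 4 * np.sqrt(n)  # binomial 4-sigma

    def test_msd_matches_propagator(self):
        # free diffusion: per-axis displacement variance = 2 D t within 3 sd
        # short horizon + deep box so reflections barely touch the ensemble
        d, t_lines = 2.0, 150
        cfg = p.paper_scan_config(
            n_lines=t_lines, n_particles=600, burn_in_s=0.0, seed=9,
            d_left=d, d_right=d, brightness=0.0, background=0.0,
            box_ly_um=8.0, box_lz_um=10.0, box_pad_um=3.0,
        )
        res = p.simulate_carpet(cfg)
        t = t_lines * cfg.scan.line_period_s
        disp = res.final_positions - res.initial_positions
        expected = 2 * d * t
        for axis in range(3):
            var = disp[:, axis].var(ddof=1)
            sd = expected * np.sqrt(2.0 / (len(disp) - 1))
            assert abs(var - expected) < 3 * sd

    def test_mean_count_matches_expected_intensity(self):
        cfg = tiny_config(n_lines=4000, brightness=0.5, background=0.05)
        res = p.simulate_carpet(cfg)
        mean = res.carpet.counts.mean()
        mu = res.mean_expected_intensity
        sd = np.sqrt(mu / res.carpet.counts.size)
        assert abs(mean - mu) < 4 * sd

    def test_compartment_labels_follow_barrier(self):
        cfg = tiny_config(barrier_x_um=1.55, n_lines=1100)
        res = p.simulate_carpet(cfg)
        labels = res.carpet.labels
        assert labels[:16] == ("nucleus",) * 16
        assert labels[16:] == ("cytoplasm",) * 16


class TestKeq:
    def test_passive_equilibrium_is_unity(self):
        cfg = tiny_config(barrier_x_um=1.55, p_cross=0.2, n_particles=200,
                          burn_in_s=1.0)
        keq = p.steady_state_keq(cfg, horizon_s=4.0)
        assert keq == pytest.approx(1.0, abs=0.25)

    def test_active_import_concentrates_left(self):
        cfg = tiny_config(
            barrier_x_um=1.55, p_cross=0.02, n_particles=200, burn_in_s=2.0,
            active=p.ActiveTransport(enabled=True, direction="right_to_left",
                                     p_active=0.5, translocation_mean_s=0.005),
        )
        keq = p.steady_state_keq(cfg, horizon_s=4.0)
        assert keq > 1.5


class TestFirstPassage:
    CFG = dict(barrier_x_um=1.55, n_lines=100)

    def test_impenetrable_barrier_all_censored(self):
        cfg = tiny_config(p_cross=0.0, **self.CFG)
        res = p.mean_crossing_time(cfg, 0.5, n_rep=100, horizon_s=0.2)
        assert res.mean_s is None
        assert res.n_censored == 100

    def test_free_passage_matches_independent_walk_oracle(self):
        # independent numpy 1-D reflected walk, dwell-sized steps
        cfg = tiny_config(p_cross=1.0, d_left=12.5, d_right=12.5, **self.CFG)
        res = p.mean_crossing_time(cfg, 0.5, n_rep=400, horizon_s=2.0, seed=77)

        rng = np.random.default_rng(123)
        dt = cfg.scan.pixel_dwell_s
        sig = np.sqrt(2 * 12.5 * dt)
        xmin, _ = cfg.x_bounds
        n_steps = int(2.0 / dt)
        times = []
        for _ in range(400):
            x = cfg.barrier_x_um - 0.5
            steps = rng.normal(0.0, sig, n_steps)
            for i in range(n_steps):
                x += steps[i]
                if x < xmin:
                    x = 2 * xmin - x
                if x >= cfg.barrier_x_um:
                    times.append((i + 1) * dt)
                    break
        oracle = np.mean(times)
        se = np.std(times, ddof=1) / np.sqrt(len(times))
        se_tot = np.hypot(se, res.sd_s / np.sqrt(res.n_crossed))
        assert abs(res.mean_s - oracle) < 2.5 * se_tot

    def test_monotone_in_permeability(self):
        means = []
        for pc in (0.01, 0.1, 1.0):
            cfg = tiny_config(p_cross=pc, **self.CFG)
            res = p.mean_crossing_time(cfg, 0.5, n_rep=300, horizon_s=5.0, seed=7)
            means.append(res.mean_s)
        assert means[0] > means[1] > means[2]


class TestCalibration:
    def test_free_limit_returns_unity(self):
        cfg = tiny_config(barrier_x_um=1.55, n_lines=100, d_left=12.5, d_right=12.5)
        free = p.mean_crossing_time(cfg, 0.5, n_rep=300, horizon_s=2.0, seed=5)
        pc, achieved = p.calibrate_permeability(free.mean_s, cfg, seed=5)
        assert pc == pytest.approx(1.0)

    def test_target_reached_within_tolerance_and_monotone(self):
        cfg = tiny_config(barrier_x_um=1.55, n_lines=100)
        p1, a1 = p.calibrate_permeability(0.25, cfg, n_rep=200, seed=11)
        assert 0 < p1 < 1
        assert a1 == pytest.approx(0.25, rel=0.1)
        # re-simulation at the calibrated value reproduces the target
        check = p.mean_crossing_time(
            replace(cfg, p_cross=p1), 0.5, n_rep=300, horizon_s=5.0, seed=99
        )
        assert check.mean_s == pytest.approx(0.25, rel=0.25)
        # doubling the target softens the barrier further
        p2, _ = p.calibrate_permeability(0.5, cfg, n_rep=200, seed=11)
        assert p2 < p1

    def test_infeasible_target(self):
        cfg = tiny_config(barrier_x_um=1.55, n_lines=100)
        with pytest.raises(InfeasibleTargetError):
            p.calibrate_permeability(1e-4, cfg, seed=3)
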