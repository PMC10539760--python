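"""Replica-exchange torsional sampler: ladders, moves, reports."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ligandconf.constants import R_KCAL
from ligandconf.rex import (
    ReplicaLadder,
    TorsionPotential,
    assign_wells,
    barrier_report,
    build_ladder,
    exchange_accept,
    free_energy_profile,
    radial_series,
    run_rex,
    torsion_histogram,
    wrap_angle,
)
from ligandconf.synthetic import gen_torsion_potential


class TestPotential:
    def test_periodicity(self):
        pot = gen_torsion_potential("hindered_biaryl")
        phis = np.linspace(-180, 180, 37)
        np.testing.assert_allclose(pot(phis), pot(phis + 360.0), atol=1e-12)

    def test_threefold_minima_equal_depth(self):
        pot = gen_torsion_potential("flexible_threefold")
        rep = barrier_report(pot)
        assert len(rep.minima) == 3
        assert np.ptp(rep.minima_energies) < 1e-9

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            gen_torsion_potential("nonexistent")

    def test_single_cosine_barrier_is_amplitude(self):
        pot = TorsionPotential(terms=((1, 4.0, 0.0),))
        rep = barrier_report(pot)
        assert len(rep.minima) == 1
        assert rep.headline_barrier == pytest.approx(4.0, abs=1e-6)


class TestBarrierReport:
    def test_hindered_biaryl_lower_barrier_calibrated(self):
        rep = barrier_report(gen_torsion_potential("hindered_biaryl"))
        assert rep.headline_barrier == pytest.approx(20.0, abs=0.01)
        assert len(rep.minima) == 2
        # symmetric double well near +/-90 with two unequal saddles
        assert rep.minima[0] == pytest.approx(-rep.minima[1], abs=1e-6)
        assert abs(abs(rep.minima[0]) - 90.0) < 10.0
        assert max(rep.saddle_energies) > min(rep.saddle_energies)

    def test_desmethyl_barrier_below_six(self):
        rep = barrier_report(gen_torsion_potential("desmethyl"))
        assert rep.headline_barrier < 6.0

    def test_flat_potential_flagged_degenerate(self):
        rep = barrier_report(TorsionPotential(terms=((1, 0.0, 0.0),)))
        assert rep.degenerate and rep.headline_barrier == 0.0


class TestLadder:
    def test_geometric_spacing_with_exact_endpoints(self):
        lad = build_ladder(300.0, 1263.0, 12)
        temps = np.array(lad.temperatures)
        assert temps[0] == 300.0 and temps[-1] == 1263.0
        ratios = temps[1:] / temps[:-1]
        assert np.ptp(ratios) < 1e-9

    def test_twenty_replica_ladder_endpoints(self):
        lad = build_ladder(300.0, 3302.0, 20)
        assert lad.temperatures[0] == 300.0
        assert lad.temperatures[-1] == 3302.0
        assert len(lad) == 20

    def test_degenerate_ladder(self):
        lad = build_ladder(300.0, 300.0, 5)
        assert lad.temperatures == (300.0,) * 5

    def test_zero_replicas_rejected(self):
        with pytest.raises(ValueError):
            build_ladder(300.0, 1000.0, 0)


class TestExchangeAccept:
    def test_equal_energies_always_accepted(self):
        assert exchange_accept(3.0, 3.0, 300.0, 600.0, 0.999999)

    def test_equal_temperatures_always_accepted(self):
        assert exchange_accept(25.0, 0.0, 300.0, 300.0, 0.999999)

    def test_empirical_frequency_matches_formula(self):
        e_i, e_j, t_i, t_j = 0.0, 1.0, 300.0, 3300.0
        p = np.exp((1 / (R_KCAL * t_i) - 1 / (R_KCAL * t_j)) * (e_i - e_j))
        rng = np.random.default_rng(7)
        n = 100_000
        draws = rng.uniform(size=n)
        freq = np.mean([exchange_accept(e_i, e_j, t_i, t_j, u) for u in draws])
        assert abs(freq - p) < 3 * np.sqrt(p * (1 - p) / n)


class TestSampler:
    def test_bit_identical_under_fixed_seed(self):
        pot = gen_torsion_potential("flexible_threefold")
        lad = build_ladder(300.0, 900.0, 4)
        a = run_rex(pot, lad, sweeps=2000, seed=11)
        b = run_rex(pot, lad, sweeps=2000, seed=11)
        np.testing.assert_array_equal(a.angles, b.angles)
        np.testing.assert_array_equal(a.walker_of_slot, b.walker_of_slot)

    def test_angles_stay_wrapped(self):
        pot = gen_torsion_potential("flexible_threefold")
        traj = run_rex(pot, build_ladder(300.0, 300.0, 1), sweeps=5000, seed=3)
        assert np.all(traj.angles >= -180.0) and np.all(traj.angles < 180.0)

    def test_two_state_occupancy_matches_boltzmann(self):
        # asymmetric double well: dG = 0.655 kcal/mol => 75/25 at 300 K
        dG = R_KCAL * 300.0 * np.log(3.0)
        # one-fold term with 90-degree phase splits the +/-90 well depths by ~dG
        pot = TorsionPotential(terms=((2, 2.0, 0.0), (1, dG, 90.0)))
        rep = barrier_report(pot)
        depths = np.array(rep.minima_energies)
        p_expected = np.exp(-(depths - depths.min()) / (R_KCAL * 300.0))
        p_expected /= p_expected.sum()
        traj = run_rex(pot, build_ladder(300.0, 300.0, 1), sweeps=100_000, seed=5)
        wells = assign_wells(traj.base_angles(burn_in=0.1), rep)
        occ = np.bincount(wells, minlength=2) / wells.size
        # binomial 3-sigma on ~ effective sample count from well transitions
        n_trans = np.count_nonzero(np.diff(wells))
        se = np.sqrt(p_expected[0] * (1 - p_expected[0]) / max(n_trans, 1))
        assert abs(occ[0] - p_expected[0]) < max(3 * se, 0.03)

    def test_raising_ladder_top_does_not_reduce_transitions(self):
        pot = gen_torsion_potential("desmethyl")
        medians = []
        for t_max in (400.0, 3300.0):
            counts = []
            for seed in range(20):
                traj = run_rex(pot, build_ladder(300.0, t_max, 6), sweeps=5000, seed=seed)
                rep = barrier_report(pot)
                wells = assign_wells(traj.base_angles(burn_in=0.1), rep)
                counts.append(np.count_nonzero(np.diff(wells)))
            medians.append(np.median(counts))
        assert medians[1] >= medians[0]


class TestHistogramAndProfile:
    def test_counts_sum_to_retained_samples(self):
        pot = gen_torsion_potential("flexible_threefold")
        traj = run_rex(pot, build_ladder(300.0, 300.0, 1), sweeps=4000, seed=2)
        edges, counts = torsion_histogram(traj, bins=36, burn_in=0.25)
        assert counts.sum() == traj.base_angles(0.25).size

    def test_subsampling_to_report_frame_count(self):
        pot = gen_torsion_potential("flexible_threefold")
        traj = run_rex(pot, build_ladder(300.0, 300.0, 1), sweeps=5000, seed=2)
        _, counts = torsion_histogram(traj, bins=36, burn_in=0.0, max_samples=1002)
        assert counts.sum() == 1002

    def test_threefold_histogram_has_three_modes_120_apart(self):
        pot = gen_torsion_potential("flexible_threefold")
        traj = run_rex(pot, build_ladder(300.0, 300.0, 1), sweeps=50_000, seed=4)
        edges, counts = torsion_histogram(traj, bins=72, burn_in=0.1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        rep = barrier_report(pot)
        wells = assign_wells(centers, rep)
        modes = sorted(centers[wells == j][np.argmax(counts[wells == j])] for j in range(3))
        gaps = np.diff(modes)
        assert np.all(np.abs(gaps - 120.0) < 15.0)

    def test_equal_counts_give_zero_delta_g(self):
        _, dg = free_energy_profile(np.array([50, 50]), 300.0)
        assert dg[0] == dg[1] == 0.0

    def test_three_to_one_ratio_gives_rt_ln3(self):
        _, dg = free_energy_profile(np.array([300, 100]), 300.0)
        assert dg[1] - dg[0] == pytest.approx(R_KCAL * 300.0 * np.log(3.0))

    def test_empty_bins_masked_not_infinite(self):
        _, dg = free_energy_profile(np.array([10, 0, 5]), 300.0)
        assert np.isnan(dg[1]) and np.isfinite(dg[0])

    def test_all_zero_histogram_rejected(self):
        with pytest.raises(ValueError):
            free_energy_profile(np.zeros(4), 300.0)


class TestRadialSeries:
    def test_radius_increases_and_endpoints_flagged(self):
        pot = gen_torsion_potential("flexible_threefold")
        traj = run_rex(pot, build_ladder(300.0, 300.0, 1), sweeps=500, seed=1)
        series = radial_series(traj)
        assert len(series) == 500
        radii = [r for r, _, _ in series]
        assert radii == sorted(radii)
        flags = [f for _, _, f in series]
        assert flags[0] and flags[-1] and not any(flags[1:-1])


class TestWrap:
    @given(st.floats(min_value=-1e4, max_value=1e4))
    def test_wrap_range_and_idempotence(self, phi):
        w = float(wrap_angle(phi))
        assert -180.0 <= w < 180.0
        assert float(wrap_angle(w)) == pytest.approx(w)
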