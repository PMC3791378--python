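"""Event-driven simulator: steric exclusion, moves, binding kinetics."""

import math
import random

import numpy as np
import pytest
from scipy import stats as sps

import fdcrowd as fd
from fdcrowd.simulator import SimulationError, Simulator
from fdcrowd.species import TFSpecies


def circular_intervals_disjoint(positions, footprint, L):
    """Independent interval-overlap checker on a circle."""
    cells = set()
    for p in positions:
        for j in range(footprint):
            cell = (p + j) % L
            if cell in cells:
                return False
            cells.add(cell)
    return True


def frozen_obstacle(position, footprint=46):
    """A molecule pinned at ``position`` for the whole run (never expires)."""
    return TFSpecies(
        name=f"block@{position}",
        copy_number=1,
        footprint=footprint,
        k_assoc=1.0,
        move_probs=(0.0, 0.0, 0.0, 1.0),
        tau0=1e12,
        initial_positions=[position],
    )


class TestInit:
    def test_no_immobile_molecules_no_initial_occupancy(self, flat_single_molecule):
        genome, species = flat_single_molecule
        sim = Simulator(genome, species, seed=0)
        assert sim.coverage_fraction() == 0.0
        assert all(p == -1 for p in sim.pos)

    @pytest.mark.parametrize("seed", range(0, 1000, 50))
    def test_immobile_placements_never_overlap(self, seed, small_genome):
        species = [fd.noncognate_species(18, 0.0, mobile=False)]
        sim = Simulator(small_genome, species, seed=seed)
        assert circular_intervals_disjoint(sim.pos, 46, small_genome.length)
        sim.audit()

    def test_many_seeds_of_dense_immobile_placement(self, small_genome):
        # lighter per-seed check across 1000 seeds
        species = [fd.noncognate_species(10, 0.0, mobile=False)]
        for seed in range(1000):
            sim = Simulator(small_genome, species, seed=seed)
            assert circular_intervals_disjoint(sim.pos, 46, small_genome.length)

    def test_overpacked_genome_reports_achievable_coverage(self):
        genome = fd.generate_genome(500, seed=1)
        species = [fd.noncognate_species(11, 0.0, mobile=False)]  # 506 bp demand
        with pytest.raises(SimulationError, match="achievable coverage"):
            Simulator(genome, species, seed=3, max_placement_tries=200)

    def test_init_bit_reproducible(self, small_genome):
        species = [fd.noncognate_species(12, 0.0, mobile=False)]
        a = Simulator(small_genome, species, seed=42)
        b = Simulator(small_genome, species, seed=42)
        assert a.pos == b.pos and a.occ == b.occ


class TestAttemptBind:
    def test_always_succeeds_on_empty_dna(self, flat_single_molecule):
        genome, species = flat_single_molecule
        for seed in range(20):
            sim = Simulator(genome, species, seed=seed)
            assert sim._attempt_bind(0, 0.0)
            sim.audit()

    def test_always_fails_on_fully_covered_dna(self):
        genome = fd.generate_genome(460, seed=2, site_position=100)
        tiling = TFSpecies(
            name="tiling", copy_number=10, footprint=46, k_assoc=1.0,
            move_probs=(0.0, 0.0, 0.0, 1.0), tau0=1e12,
            initial_positions=[46 * i for i in range(10)],
        )
        probe = fd.noncognate_species(1, 1800.0)
        sim = Simulator(genome, [tiling, probe], seed=5)
        assert sim.coverage_fraction() == 1.0
        m = sim.sp.index(1)
        for _ in range(200):
            assert not sim._attempt_bind(m, 0.0)

    def test_acceptance_frequency_matches_vacancy_fraction(self, small_genome):
        block = fd.noncognate_species(15, 0.0, mobile=False)
        probe = fd.noncognate_species(1, 1800.0)
        sim = Simulator(small_genome, [block, probe], seed=7)
        m = sim.sp.index(1)
        vacant = sim.vacant_position_count(46)  # exhaustive oracle
        p = vacant / small_genome.n_positions(46)
        n, hits = 100_000, 0
        for _ in range(n):
            if sim._attempt_bind(m, 0.0):
                hits += 1
                sim._vacate(1, m, 0.0)
        assert abs(hits / n - p) <= 3 * math.sqrt(p * (1 - p) / n)


class TestStepMolecule:
    def _drive(self, sim, m, n_steps, classify):
        counts = {"left": 0, "right": 0, "stay": 0, "unbind": 0}
        t = 0.0
        while sum(counts.values()) < n_steps:
            t += 1.0
            if sim.pos[m] < 0:
                sim._attempt_bind(m, t)
            else:
                before = sim.pos[m]
                sim._step_bound(m, t)
                counts[classify(before, sim.pos[m], sim.L)] += 1
        return counts

    @staticmethod
    def _classify(before, after, L):
        if after < 0:
            return "unbind"
        if after == (before - 1) % L:
            return "left"
        if after == (before + 1) % L:
            return "right"
        return "stay"

    def test_unbind_only_species_always_unbinds(self, flat_single_molecule):
        genome, _ = flat_single_molecule
        sp = fd.noncognate_species(1, 1800.0, move_probs=(0.0, 0.0, 0.0, 1.0))
        sim = Simulator(genome, [sp], seed=9)
        counts = self._drive(sim, 0, 2000, self._classify)
        assert counts["unbind"] == 2000

    def test_outcome_frequencies_match_move_probs(self, flat_single_molecule):
        genome, _ = flat_single_molecule
        probs = (0.3, 0.2, 0.0, 0.5)
        sp = fd.noncognate_species(1, 1800.0, move_probs=probs)
        sim = Simulator(genome, [sp], seed=11)
        n = 100_000
        counts = self._drive(sim, 0, n, self._classify)
        for key, p in zip(("left", "right", "stay", "unbind"), (0.3, 0.2, 0.0, 0.5)):
            assert abs(counts[key] / n - p) <= 3 * math.sqrt(max(p * (1 - p), 1e-9) / n) + 1e-9

    def test_hop_displacement_within_range_and_nonzero(self, flat_single_molecule):
        genome, _ = flat_single_molecule
        sp = fd.noncognate_species(
            1, 1800.0, move_probs=(0.0, 0.0, 1.0, 0.0), hop_range=7
        )
        sim = Simulator(genome, [sp], seed=13)
        sim._attempt_bind(0, 0.0)
        L = genome.length
        for _ in range(5000):
            before = sim.pos[0]
            sim._step_bound(0, 1.0)
            d = (sim.pos[0] - before + L // 2) % L - L // 2
            assert 1 <= abs(d) <= 7

    def test_slide_into_occupied_neighbor_never_overlaps(self):
        genome = fd.generate_genome(300, seed=4)
        block = frozen_obstacle(100, footprint=46)
        walker = fd.noncognate_species(
            1, 1800.0, footprint=46, move_probs=(0.5, 0.5, 0.0, 0.0)
        )
        walker.initial_positions = [54]  # right edge flush against the obstacle
        sim = Simulator(genome, [block, walker], seed=17)
        m = sim.sp.index(1)
        for step in range(2000):
            sim._step_bound(m, float(step))
        sim.audit()
        assert sim.pos[0] == 100  # obstacle untouched

    def test_step_on_free_molecule_rejected(self, flat_single_molecule):
        genome, species = flat_single_molecule
        sim = Simulator(genome, species, seed=1)
        with pytest.raises(SimulationError, match="free"):
            sim._step_bound(0, 0.0)


class TestRunSimulation:
    def test_zero_duration_is_censored_and_empty(self, small_genome, small_landscape):
        species = [fd.cognate_species(1, 4.19, small_landscape)]
        traj = fd.run_simulation(small_genome, species, 0.0, seed=1)
        assert traj.censored and traj.first_passage is None
        assert traj.target_intervals == [] and traj.occupancy_fraction == 0.0

    def test_preplaced_cognate_at_target_has_zero_first_passage(
        self, small_genome, small_landscape
    ):
        species = [
            fd.cognate_species(
                1, 4.19, small_landscape,
                initial_positions=[small_genome.target_start],
            )
        ]
        traj = fd.run_simulation(small_genome, species, 0.5, seed=1)
        assert traj.first_passage == 0.0 and not traj.censored

    def test_same_seed_bit_reproducible(self, small_genome, small_landscape):
        species = lambda: [
            fd.cognate_species(2, 6.1, small_landscape),
            fd.noncognate_species(5, 2571.0),
        ]
        a = fd.run_simulation(small_genome, species(), 2.0, seed=99)
        b = fd.run_simulation(small_genome, species(), 2.0, seed=99)
        assert a.first_passage == b.first_passage
        assert a.target_intervals == b.target_intervals
        assert a.occupancy_fraction == b.occupancy_fraction
        assert a.mean_coverage == b.mean_coverage
        assert a.n_events == b.n_events

    def test_steric_audit_and_conservation_after_crowded_run(self, small_genome):
        species = [
            fd.noncognate_species(20, 3600.0),
            fd.noncognate_species(5, 0.0, mobile=False),
        ]
        sim = Simulator(small_genome, species, seed=23)
        sim.run(1.0)
        sim.audit()

    def test_immobile_positions_unchanged_by_dynamics(self, small_genome):
        species = [
            fd.noncognate_species(8, 0.0, mobile=False),
            fd.noncognate_species(10, 2000.0),
        ]
        sim = Simulator(small_genome, species, seed=29)
        before = [p for m, p in enumerate(sim.pos) if not sim._mobile_of[m]]
        sim.run(1.0)
        after = [p for m, p in enumerate(sim.pos) if not sim._mobile_of[m]]
        assert before == after

    def test_coverage_fraction_arithmetic(self):
        genome = fd.generate_genome(100, gc=0.5, seed=6, site_position=10)
        block = fd.noncognate_species(1, 0.0, mobile=False)
        sim = Simulator(genome, [block], seed=1)
        assert sim.coverage_fraction() == pytest.approx(0.46)

    def test_event_times_never_regress(self, small_genome):
        species = [fd.noncognate_species(10, 2000.0)]
        sim = Simulator(small_genome, species, seed=31)
        sim.run(0.5)  # _accumulate raises on regression
        assert sim.time == 0.5


class TestStationaryBehaviour:
    def test_single_bound_walker_visits_uniformly_on_circle(self):
        """Flat landscape + symmetric slides => uniform stationary law."""
        genome = fd.generate_genome(50, seed=8, site_position=5)
        sp = fd.noncognate_species(
            1, 1800.0, footprint=5,
            move_probs=(0.45, 0.45, 0.1, 0.0), hop_range=10, tau0=1e-3,
        )
        sp.initial_positions = [0]
        sim = Simulator(genome, [sp], seed=37)
        counts = np.zeros(50, dtype=int)
        t = 0.0
        for _ in range(2500):
            t += 1.0  # ~1000 moves between samples: well mixed
            sim.advance_to(t)
            counts[sim.pos[0]] += 1
        assert sps.chisquare(counts).pvalue > 1e-4

    def test_calibrated_rate_gives_90pct_bound(self, flat_single_molecule):
        genome, species = flat_single_molecule
        k = fd.calibrate_association_rate(species[0].tau0, species[0].p_unbind)
        assert k == pytest.approx(1800.0)
        traj = fd.run_simulation(genome, species, 120.0, seed=41)
        assert traj.bound_fraction["nc_mobile"] == pytest.approx(0.90, abs=0.03)


class TestExclusionWindow:
    def test_window_arithmetic_is_66bp(self):
        assert fd.exclusion_window(21, 46) == 66

    @pytest.mark.parametrize("offset", [-45, -20, 0, 20])
    def test_obstacle_inside_window_blocks_target_forever(
        self, small_genome, small_landscape, offset
    ):
        ts = small_genome.target_start
        species = [
            frozen_obstacle(ts + offset),
            fd.cognate_species(3, 50.0, small_landscape),
        ]
        traj = fd.run_simulation(
            small_genome, species, 2.0, seed=43, stop_at_first_passage=True
        )
        assert traj.censored

    @pytest.mark.parametrize("offset", [-46, 21])
    def test_obstacle_just_outside_window_permits_binding(
        self, small_genome, small_landscape, offset
    ):
        ts = small_genome.target_start
        species = [
            frozen_obstacle(ts + offset),
            fd.cognate_species(5, 50.0, small_landscape),
        ]
        traj = fd.run_simulation(
            small_genome, species, 60.0, seed=47, stop_at_first_passage=True
        )
        assert not traj.censored
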