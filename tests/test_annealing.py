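"""Annealing schedule, Langevin thermostat, and restrained toy dynamics."""

import numpy as np
import pytest

from ubnmr.annealing import (
    AnnealSchedule,
    HarmonicBondTerm,
    RestraintTerm,
    run,
    swap_analysis,
    temperature_at,
)
from ubnmr.restraints import ContactRestraint, CoordinateFrame, WallRestraint, wall_energy


def chain_frame(n=10, spacing=0.4, mass=100.0):
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) * spacing
    return CoordinateFrame(pos, np.full(n, mass), {i: np.array([i]) for i in range(n)})


def chain_bonds(n=10, r0=0.4, k=1000.0):
    return HarmonicBondTerm([(i, i + 1, r0, k) for i in range(n - 1)])


def wall_term(wall):
    def fn(frames):
        e, f = wall_energy(frames[0], wall)
        return e, [f] + [np.zeros_like(x.positions) for x in frames[1:]]

    return RestraintTerm("wall", fn)


class TestSchedule:
    def test_printed_checkpoints(self):
        s = AnnealSchedule()
        assert temperature_at(s, 0.0) == 300.0
        assert temperature_at(s, 400.0) == 500.0
        assert temperature_at(s, 450.0) == 500.0
        assert temperature_at(s, 900.0) == 300.0

    def test_periodic_over_cycles(self):
        s = AnnealSchedule()
        assert temperature_at(s, s.cycle_ps) == 300.0
        assert temperature_at(s, 2 * s.cycle_ps + 200.0) == temperature_at(s, 200.0)

    def test_fifty_cycles_span_fifty_ns(self):
        s = AnnealSchedule(n_cycles=50)
        assert s.cycle_ps == 1000.0
        assert s.total_ps == 50000.0  # 50 ns

    def test_rejects_nonpositive_segments(self):
        with pytest.raises(ValueError):
            AnnealSchedule(ramp_up_ps=0.0)


class TestRun:
    def small_schedule(self, n_cycles=2, t_high=500.0, t_low=300.0):
        return AnnealSchedule(t_low, t_high, 2.0, 1.0, 2.0, 1.0, n_cycles)

    def test_static_at_zero_temperature_without_forces(self):
        frame = chain_frame(4)
        start = frame.positions.copy()
        sched = AnnealSchedule(1e-12, 1e-12, 2.0, 1.0, 2.0, 1.0, 1)
        traj = run([frame], [], sched, seed=1, dt_ps=0.01, sample_stride=10)
        assert frame.positions == pytest.approx(start, abs=1e-6)
        assert not traj.aborted

    def test_same_seed_reproduces_trajectory(self):
        out = []
        for _ in range(2):
            frame = chain_frame()
            traj = run(
                [frame], [chain_bonds()], self.small_schedule(), seed=42,
                dt_ps=0.005, sample_stride=10,
            )
            out.append((frame.positions.copy(), traj.kinetic_temp_K.copy()))
        assert np.array_equal(out[0][0], out[1][0])
        assert np.array_equal(out[0][1], out[1][1])

    def test_equipartition_at_constant_temperature(self):
        frame = chain_frame()
        sched = AnnealSchedule(300.0, 300.0, 5.0, 5.0, 5.0, 5.0, 10)
        traj = run([frame], [chain_bonds()], sched, seed=3, dt_ps=0.005, sample_stride=20)
        burn = traj.times_ps > 50.0
        mean_t = traj.kinetic_temp_K[burn].mean()
        assert abs(mean_t - 300.0) / 300.0 < 0.03

    def test_energy_bookkeeping_sums_terms(self):
        frame = chain_frame()
        wall = WallRestraint(k=20.0, d_max_nm=1.0, group_a=[0, 1], group_b=[8, 9])
        traj = run(
            [frame], [chain_bonds(), wall_term(wall)], self.small_schedule(),
            seed=5, dt_ps=0.005, sample_stride=10,
        )
        assert traj.energies["total_restraint"] == pytest.approx(
            traj.energies["wall"], rel=1e-12
        )

    def test_violated_wall_relaxes_under_annealing(self):
        # stretched dimer inside a wall: terminal wall energy below initial
        # in >= 95 of 100 seeded runs
        wins = 0
        for seed in range(100):
            pos = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
            frame = CoordinateFrame(pos, np.full(2, 100.0), {0: np.array([0]), 1: np.array([1])})
            wall = WallRestraint(k=20.0, d_max_nm=1.0, group_a=[0], group_b=[1])
            e0, _ = wall_energy(frame, wall)
            sched = AnnealSchedule(300.0, 500.0, 1.0, 0.5, 1.0, 0.5, 1)
            traj = run([frame], [wall_term(wall)], sched, seed=seed, dt_ps=0.005, sample_stride=20)
            if traj.energies["wall"][-1] < e0:
                wins += 1
        assert wins >= 95

    def test_low_temperature_frames_flagged(self):
        frame = chain_frame()
        sched = self.small_schedule()
        traj = run([frame], [chain_bonds()], sched, seed=7, dt_ps=0.01, sample_stride=25)
        assert traj.low_t_sample.any()
        in_cycle = traj.times_ps[traj.low_t_sample] % sched.cycle_ps
        ok = (in_cycle > sched.cycle_ps - sched.hold_low_ps) | (in_cycle == 0.0)
        assert ok.all()


class TestSwapAnalysis:
    def two_arm_traj(self):
        """Constructed contact record: residue 0 occupies the pocket for
        the first 3 cycles, then residue 1 takes over."""
        sched = AnnealSchedule(300.0, 400.0, 1.0, 1.0, 1.0, 1.0, 8)
        times = np.arange(1, 33) * (sched.cycle_ps / 4)
        in_cycle = times % sched.cycle_ps
        low = (in_cycle > sched.cycle_ps - sched.hold_low_ps) | (in_cycle == 0.0)
        cyc = np.ceil(times / sched.cycle_ps).astype(int)
        s_a = np.where(cyc <= 3, 2.0, 0.0)
        s_b = np.where(cyc >= 5, 2.0, 0.0)
        from ubnmr.annealing import TrajectoryRecord

        traj = TrajectoryRecord(
            times_ps=times,
            target_temp_K=np.full_like(times, 300.0),
            kinetic_temp_K=np.full_like(times, 300.0),
            energies={},
            contact_counts={0: s_a, 1: s_b},
            low_t_sample=low,
        )
        return traj, sched

    def test_handoff_detected(self):
        traj, sched = self.two_arm_traj()
        out = swap_analysis(traj, sched, 0, 1)
        assert out["occupancy_a"].tolist() == [True] * 3 + [False] * 5
        assert out["occupancy_b"].tolist() == [False] * 4 + [True] * 4
        assert out["a_leaves_cycle"] == 3
        assert out["b_enters_cycle"] == 4

    def test_permanent_occupancy_all_true(self):
        traj, sched = self.two_arm_traj()
        traj.contact_counts[0][:] = 2.0
        out = swap_analysis(traj, sched, 0, 1)
        assert out["occupancy_a"].all()
        assert out["a_leaves_cycle"] is None

    def test_never_in_pocket_all_false(self):
        traj, sched = self.two_arm_traj()
        traj.contact_counts[0][:] = 0.0
        traj.contact_counts[1][:] = 0.0
        out = swap_analysis(traj, sched, 0, 1)
        assert not out["occupancy_a"].any()
        assert not out["occupancy_b"].any()
        assert out["b_enters_cycle"] is None

    def test_missing_residue_rejected(self):
        traj, sched = self.two_arm_traj()
        with pytest.raises(ValueError):
            swap_analysis(traj, sched, 0, 9)


class TestRampedRun:
    def test_ramped_wall_constant_reaches_stop(self):
        from ubnmr.restraints import RampSchedule

        frame = chain_frame(4)
        wall = WallRestraint(k=20.0, d_max_nm=0.2, group_a=[0], group_b=[3])
        term = wall_term(wall)
        term.ramp = RampSchedule("k", 0.0, 20.0, 1.0)
        sched = AnnealSchedule(300.0, 300.0, 1.0, 1.0, 1.0, 1.0, 1)
        run([frame], [chain_bonds(4), term], sched, seed=2, dt_ps=0.01,
            sample_stride=10, ramp_stride=10)
        assert term.scale == 1.0  # ramp completed

    def test_end_to_end_contact_handoff_toy(self):
        """Two-arm bead model: arm A starts in the pocket, a contact
        restraint targeting arm B plus annealing moves B into the pocket."""
        # beads: 0 pocket, 1 arm A (in pocket), 2 arm B (far), 3 anchor
        pos = np.array(
            [[0.0, 0.0, 0.0], [0.3, 0.0, 0.0], [2.5, 0.0, 0.0], [1.0, 1.0, 0.0]]
        )
        frame = CoordinateFrame(pos, np.full(4, 50.0), {i: np.array([i]) for i in range(4)})
        bonds = HarmonicBondTerm([(3, 1, 1.2, 100.0), (3, 2, 1.2, 100.0)])
        contact_b = ContactRestraint(active_a=[2], active_b=[0], r0_nm=0.65, k=100.0, smooth=True)
        from ubnmr.restraints import contact_restraint_energy

        cterm = RestraintTerm("contact_b", lambda fs: contact_restraint_energy(fs, contact_b))
        report = ContactRestraint(active_a=[1, 2], active_b=[0], r0_nm=0.65, k=0.0, smooth=False)
        sched = AnnealSchedule(300.0, 500.0, 2.0, 1.0, 2.0, 1.0, 6)
        traj = run(
            [frame], [bonds, cterm], sched, seed=11, dt_ps=0.005,
            sample_stride=20, contact_term=report,
        )
        out = swap_analysis(traj, sched, 1, 2)
        # arm B ends up occupying the pocket
        assert out["b_enters_cycle"] is not None
        assert out["occupancy_b"][-1]
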