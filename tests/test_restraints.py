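"""Restraint potentials: printed-constant arithmetic, gradients, replica
averaging, contact counting and ramp schedules."""

import numpy as np
import pytest

from conftest import finite_difference_forces
from ubnmr.restraints import (
    ContactRestraint,
    CoordinateFrame,
    CSRestraintSet,
    DEFAULT_RAMPS,
    LinearToyPredictor,
    NOERestraintSet,
    RampSchedule,
    WallRestraint,
    apply_ramp,
    binary_contact_satisfied,
    contact_count,
    contact_restraint_energy,
    cs_energy,
    noe_energy,
    wall_energy,
)


def two_bead_frame(d_nm, masses=(12.0, 12.0)):
    pos = np.array([[0.0, 0.0, 0.0], [d_nm, 0.0, 0.0]])
    return CoordinateFrame(pos, np.array(masses), {0: np.array([0]), 1: np.array([1])})


class TestWallEnergy:
    def test_flat_inside_dmax(self):
        frame = two_bead_frame(1.0)
        wall = WallRestraint(k=20.0, d_max_nm=2.5, group_a=[0], group_b=[1])
        e, f = wall_energy(frame, wall)
        assert e == 0.0
        assert np.all(f == 0.0)

    def test_printed_constant_one_nm_violation(self):
        # k = 20 kJ/(mol nm^2), violation of 1 nm -> 20 kJ/mol
        frame = two_bead_frame(3.5)
        wall = WallRestraint(k=20.0, d_max_nm=2.5, group_a=[0], group_b=[1])
        e, _ = wall_energy(frame, wall)
        assert e == pytest.approx(20.0, rel=1e-12)

    def test_com_distance_is_mass_weighted(self):
        # 3 beads: group a = {0,1} unequal masses
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [5.0, 0, 0]])
        frame = CoordinateFrame(pos, np.array([1.0, 3.0, 2.0]))
        wall = WallRestraint(k=1.0, d_max_nm=0.5, group_a=[0, 1], group_b=[2])
        e, _ = wall_energy(frame, wall)
        com_a = 0.75  # (0*1 + 1*3)/4
        assert e == pytest.approx((5.0 - com_a - 0.5) ** 2, rel=1e-12)

    def test_analytic_forces_match_finite_differences(self, fresh_beads):
        frames, (ga, gb), _ = fresh_beads()
        wall = WallRestraint(k=20.0, d_max_nm=0.5, group_a=ga, group_b=gb)

        def efun(fs):
            e, f = wall_energy(fs[0], wall)
            return e, [f] + [np.zeros_like(x.positions) for x in fs[1:]]

        ana, num = finite_difference_forces(efun, frames[:1], stride=3)
        assert ana == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_rejects_overlapping_or_empty_groups(self):
        with pytest.raises(ValueError):
            WallRestraint(k=1.0, d_max_nm=1.0, group_a=[0], group_b=[0])
        with pytest.raises(ValueError):
            WallRestraint(k=1.0, d_max_nm=1.0, group_a=[], group_b=[1])


class TestNOEEnergy:
    def test_single_replica_reduces_to_per_frame_form(self, bead_fixture):
        frames, _, dists = bead_fixture
        pairs = [(i, j, d * 0.9) for i, j, d in dists]
        e_avg, _ = noe_energy(frames[:1], NOERestraintSet(pairs, beta=0.25))
        e_direct, _ = noe_energy(
            frames[:1], NOERestraintSet(pairs, beta=0.25, replica_averaged=False)
        )
        assert e_avg == pytest.approx(e_direct, rel=1e-12)

    def test_equal_replicas_effective_distance_is_r(self):
        f1 = two_bead_frame(0.45)
        f2 = two_bead_frame(0.45)
        r = NOERestraintSet([(0, 1, 0.45)], beta=2.0)
        e, _ = noe_energy([f1, f2], r)
        assert e == pytest.approx(0.0, abs=1e-14)

    def test_hand_computed_effective_distance(self):
        # replicas at r = 0.3 and 0.6 nm: d_eff = ((0.3^-6 + 0.6^-6)/2)^(-1/6)
        d_eff = ((0.3**-6 + 0.6**-6) / 2.0) ** (-1.0 / 6.0)
        assert d_eff == pytest.approx(0.336, abs=5e-4)
        f1, f2 = two_bead_frame(0.3), two_bead_frame(0.6)
        r = NOERestraintSet([(0, 1, 0.5)], beta=1.0)
        e, _ = noe_energy([f1, f2], r)
        assert e == pytest.approx((0.5 - d_eff) ** 2, rel=1e-10)

    @pytest.mark.parametrize("replica_averaged", [True, False])
    def test_forces_match_finite_differences(self, fresh_beads, replica_averaged):
        frames, _, dists = fresh_beads()
        pairs = [(i, j, d * 0.8) for i, j, d in dists]
        r = NOERestraintSet(pairs, beta=0.25, replica_averaged=replica_averaged)
        ana, num = finite_difference_forces(lambda fs: noe_energy(fs, r), frames, stride=4)
        assert ana == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_replica_permutation_invariance(self, bead_fixture):
        frames, _, dists = bead_fixture
        pairs = [(i, j, d * 0.8) for i, j, d in dists]
        r = NOERestraintSet(pairs, beta=0.25)
        e1, _ = noe_energy(frames, r)
        e2, _ = noe_energy(frames[::-1], r)
        assert e1 == pytest.approx(e2, rel=1e-14)

    def test_newtons_third_law(self, bead_fixture):
        frames, _, dists = bead_fixture
        r = NOERestraintSet([(i, j, d * 0.8) for i, j, d in dists], beta=0.25)
        _, forces = noe_energy(frames, r)
        for f in forces:
            assert np.abs(f.sum(axis=0)).max() < 1e-10

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError):
            NOERestraintSet([(0, 1, 0.4), (1, 0, 0.5)])


def make_cs_setup(n_beads=20, n_res=3, seed=0):
    rng = np.random.default_rng(seed)
    terms = {
        (k, l): (float(rng.normal()), rng.normal(size=(n_beads, 3)) * 0.1)
        for k in range(1, n_res + 1)
        for l in ("CA", "C", "HA", "HN", "N")
    }
    targets = [(k, l, float(rng.normal())) for (k, l) in terms]
    return LinearToyPredictor(terms), targets


class TestCSEnergy:
    def test_exact_predictions_give_zero(self, bead_fixture):
        frames, _, _ = bead_fixture
        pred, _ = make_cs_setup()
        shifts = pred.predict(frames[0])
        # targets = mean over replicas of predicted shifts -> zero penalty
        preds = [pred.predict(f) for f in frames]
        targets = [
            (k, l, float(np.mean([p[(k, l)][0] for p in preds])))
            for (k, l) in shifts
        ]
        e, forces = cs_energy(frames, CSRestraintSet(targets, alpha=24.0, predictor=pred))
        assert e == pytest.approx(0.0, abs=1e-18)

    def test_zero_alpha_gives_zero_energy(self, bead_fixture):
        frames, _, _ = bead_fixture
        pred, targets = make_cs_setup()
        e, _ = cs_energy(frames, CSRestraintSet(targets, alpha=0.0, predictor=pred))
        assert e == 0.0

    def test_single_replica_offset_averages_down(self):
        # M=4 replicas, one nucleus off by Delta in one replica -> alpha (Delta/4)^2
        n = 4
        frames = [two_bead_frame(0.5) for _ in range(n)]
        w = np.zeros((2, 3))
        w[0, 0] = 1.0  # shift = x-coordinate of bead 0
        pred = LinearToyPredictor({(1, "CA"): (0.0, w)})
        delta = 0.8
        frames[2].positions[0, 0] += delta
        e, _ = cs_energy(frames, CSRestraintSet([(1, "CA", 0.0)], alpha=5.0, predictor=pred))
        assert e == pytest.approx(5.0 * (delta / n) ** 2, rel=1e-12)

    def test_forces_match_finite_differences(self, fresh_beads):
        frames, _, _ = fresh_beads()
        pred, targets = make_cs_setup()
        r = CSRestraintSet(targets, alpha=2.0, predictor=pred)
        ana, num = finite_difference_forces(lambda fs: cs_energy(fs, r), frames, stride=4)
        assert ana == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_missing_nucleus_rejected_by_name(self, bead_fixture):
        frames, _, _ = bead_fixture
        pred, _ = make_cs_setup(n_res=1)
        r = CSRestraintSet([(9, "HN", 0.0)], alpha=1.0, predictor=pred)
        with pytest.raises(ValueError, match="residue 9 nucleus HN"):
            cs_energy(frames, r)

    def test_unknown_nucleus_label_rejected(self):
        pred, _ = make_cs_setup()
        with pytest.raises(ValueError):
            CSRestraintSet([(1, "CB", 0.0)], alpha=1.0, predictor=pred)


class TestContactCount:
    def contact(self, **kw):
        defaults = dict(active_a=[0, 1], active_b=[5, 6], r0_nm=0.65, k=50.0)
        defaults.update(kw)
        return ContactRestraint(**defaults)

    def frame_at(self, distances):
        # residue 0 at origin; residues 5,6 at given x-distances
        pos = np.zeros((7, 3))
        pos[5, 0] = distances[0]
        pos[6, 0] = distances[1]
        pos[1, 1] = 3.0
        return CoordinateFrame(pos, np.full(7, 12.0), {i: np.array([i]) for i in range(7)})

    def test_all_partners_far_gives_zero(self):
        frame = self.frame_at([5.0, 7.0])
        assert contact_count(frame, self.contact(), 0) == 0.0

    def test_binary_contact_counts_one_per_residue(self):
        frame = self.frame_at([0.9 * 0.65, 5.0])
        assert contact_count(frame, self.contact(), 0) == 1.0

    def test_smooth_switching_half_at_r0(self):
        frame = self.frame_at([0.65, 5.0])
        s = contact_count(frame, self.contact(smooth=True), 0)
        far = 1.0 / (1.0 + (5.0 / 0.65) ** 6)
        assert s == pytest.approx(0.5 + far, rel=1e-10)

    def test_inactive_residue_rejected(self):
        frame = self.frame_at([1.0, 1.0])
        with pytest.raises(ValueError):
            contact_count(frame, self.contact(), 3)


class TestContactRestraintEnergy:
    def separated_frames(self, n_rep, gap_nm):
        frames = []
        for m in range(n_rep):
            pos = np.zeros((4, 3))
            pos[2, 0] = gap_nm
            pos[3, 0] = gap_nm
            pos[3, 1] = 0.3
            pos[1, 1] = 0.3
            frames.append(
                CoordinateFrame(pos.copy(), np.full(4, 12.0), {i: np.array([i]) for i in range(4)})
            )
        return frames

    def contact(self, **kw):
        defaults = dict(active_a=[0, 1], active_b=[2, 3], r0_nm=0.65, k=50.0, smooth=True)
        defaults.update(kw)
        return ContactRestraint(**defaults)

    def test_all_replicas_satisfied_zero_energy(self):
        frames = self.separated_frames(3, 0.3)  # well inside r0 -> S_i ~ 2
        e, f = contact_restraint_energy(frames, self.contact())
        assert e == 0.0
        assert all(np.all(fi == 0) for fi in f)

    def test_single_satisfying_replica_suffices(self):
        frames = self.separated_frames(3, 4.0)
        frames[1] = self.separated_frames(1, 0.2)[0]  # only replica 1 in contact
        e, _ = contact_restraint_energy(frames, self.contact())
        assert e == 0.0

    def test_no_contacts_hand_evaluated_penalty(self):
        frames = self.separated_frames(2, 4.0)
        r = self.contact()
        e, _ = contact_restraint_energy(frames, r)
        # hand evaluation of the documented formula
        kappa = r.sharpness
        expected = 0.0
        for res_i in r.active_a:
            s_rep = np.array([contact_count(f, r, res_i) for f in frames])
            s_soft = np.log(np.sum(np.exp(kappa * s_rep))) / kappa
            expected += r.k * (1.0 - s_soft) ** 2
        assert e == pytest.approx(expected, rel=1e-12)
        assert e > 0

    def test_forces_match_finite_differences(self):
        frames = self.separated_frames(3, 1.1)
        r = self.contact()
        ana, num = finite_difference_forces(
            lambda fs: contact_restraint_energy(fs, r), frames, stride=1
        )
        assert ana == pytest.approx(num, rel=1e-3, abs=1e-8)

    def test_replica_permutation_invariance(self):
        frames = self.separated_frames(3, 1.1)
        frames[0].positions[2, 0] = 0.9
        r = self.contact()
        e1, _ = contact_restraint_energy(frames, r)
        e2, _ = contact_restraint_energy(frames[::-1], r)
        assert e1 == pytest.approx(e2, rel=1e-12)

    def test_binary_reporting(self):
        frames = self.separated_frames(3, 4.0)
        frames[1] = self.separated_frames(1, 0.2)[0]
        sat = binary_contact_satisfied(frames, self.contact())
        assert sat == {0: True, 1: True}


class TestRamps:
    def test_published_endpoints(self):
        assert apply_ramp(DEFAULT_RAMPS["alpha_cs"], 0) == 0.0
        assert apply_ramp(DEFAULT_RAMPS["alpha_cs"], 24) == 24.0
        assert apply_ramp(DEFAULT_RAMPS["beta_noe"], 20) == pytest.approx(2.0)
        assert apply_ramp(DEFAULT_RAMPS["k_contact"], 50) == 50.0

    def test_clamped_beyond_schedule_end(self):
        assert apply_ramp(DEFAULT_RAMPS["alpha_cs"], 1000) == 24.0

    def test_step_must_divide_range(self):
        with pytest.raises(ValueError):
            RampSchedule("bad", 0.0, 1.0, 0.3)

    def test_stepwise_values(self):
        sched = DEFAULT_RAMPS["beta_noe"]
        vals = [apply_ramp(sched, i) for i in range(sched.n_steps + 1)]
        assert vals[0] == 0.0 and vals[-1] == pytest.approx(2.0)
        assert np.allclose(np.diff(vals), 0.1)
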