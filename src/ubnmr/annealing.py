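"""Langevin dynamics with restraint energies under a simulated-annealing
temperature schedule, on coarse bead systems.

One annealing cycle ramps the thermostat linearly from a low to a high
temperature, holds, cools back down and holds again; cycling repeatedly
lets the system escape local minima while low-temperature end-of-cycle
frames are kept for analysis.  The integrator is BAOAB Langevin
(deterministic given a seed) in GROMACS-style units: nm, ps, amu, kJ/mol,
so kinetic energies come out directly in kJ/mol and the Boltzmann constant
is 0.008314 kJ/(mol K).

The driver exists to exercise the restraint mechanics end-to-end on small
bead models (anchoring-position hand-off demonstrations at toy scale); it
makes no attempt at an all-atom force field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB_KJ_PER_MOL_K
from .restraints import ContactRestraint, CoordinateFrame, contact_count

__all__ = [
    "AnnealSchedule",
    "HarmonicBondTerm",
    "RestraintTerm",
    "TrajectoryRecord",
    "temperature_at",
    "run",
    "swap_analysis",
]


@dataclass(frozen=True)
class AnnealSchedule:
    """Piecewise-linear, periodic temperature profile (K, ps)."""

    t_low: float = 300.0
    t_high: float = 500.0
    ramp_up_ps: float = 400.0
    hold_high_ps: float = 100.0
    ramp_down_ps: float = 400.0
    hold_low_ps: float = 100.0
    n_cycles: int = 50

    def __post_init__(self):
        for name in ("ramp_up_ps", "hold_high_ps", "ramp_down_ps", "hold_low_ps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_cycles < 1:
            raise ValueError("need at least one cycle")

    @property
    def cycle_ps(self) -> float:
        return (
            self.ramp_up_ps + self.hold_high_ps + self.ramp_down_ps + self.hold_low_ps
        )

    @property
    def total_ps(self) -> float:
        return self.cycle_ps * self.n_cycles


def temperature_at(schedule: AnnealSchedule, time_ps: float) -> float:
    """Thermostat target at a given time, periodic over cycles."""
    if time_ps < 0:
        raise ValueError("time must be non-negative")
    t = time_ps % schedule.cycle_ps
    s = schedule
    if t < s.ramp_up_ps:
        return s.t_low + (s.t_high - s.t_low) * t / s.ramp_up_ps
    t -= s.ramp_up_ps
    if t < s.hold_high_ps:
        return s.t_high
    t -= s.hold_high_ps
    if t < s.ramp_down_ps:
        return s.t_high + (s.t_low - s.t_high) * t / s.ramp_down_ps
    return s.t_low


class RestraintTerm:
    """Adapter binding a named restraint to its energy/forces function.

    ``fn(frames) -> (energy, [forces per replica])``; an optional ramp
    schedule rescales the published force constant k_stop down to the
    ramped value by multiplying energies and forces (all potentials here
    are linear in their force constant).
    """

    def __init__(self, name, fn, ramp=None):
        self.name = name
        self.fn = fn
        self.ramp = ramp
        self.scale = 1.0

    def set_ramp_step(self, step_index: int):
        if self.ramp is not None and self.ramp.stop > 0:
            from .restraints import apply_ramp

            self.scale = apply_ramp(self.ramp, step_index) / self.ramp.stop

    def energy_forces(self, frames):
        e, f = self.fn(frames)
        if self.scale != 1.0:
            e = e * self.scale
            f = [fi * self.scale for fi in f]
        return e, f


class HarmonicBondTerm(RestraintTerm):
    """Minimal bonded 'force field' holding bead models together:
    E = sum k_b (r - r0)^2 over bonds, applied per replica."""

    def __init__(self, bonds: list[tuple[int, int, float, float]]):
        # bonds: (i, j, r0_nm, k kJ/(mol nm^2))
        self.bonds = bonds
        self._ii = np.array([b[0] for b in bonds], dtype=int)
        self._jj = np.array([b[1] for b in bonds], dtype=int)
        self._r0 = np.array([b[2] for b in bonds])
        self._kb = np.array([b[3] for b in bonds])
        super().__init__("bonds", self._eval)

    def _eval(self, frames):
        energy = 0.0
        forces = [np.zeros_like(f.positions) for f in frames]
        for m, frame in enumerate(frames):
            dvec = frame.positions[self._ii] - frame.positions[self._jj]
            d = np.linalg.norm(dvec, axis=1)
            dev = d - self._r0
            energy += float(np.sum(self._kb * dev**2))
            g = (2.0 * self._kb * dev / d)[:, None] * dvec
            np.add.at(forces[m], self._ii, -g)
            np.add.at(forces[m], self._jj, g)
        return energy, forces


@dataclass
class TrajectoryRecord:
    times_ps: np.ndarray
    target_temp_K: np.ndarray
    kinetic_temp_K: np.ndarray
    energies: dict[str, np.ndarray]  # per-term, plus "total_restraint"
    contact_counts: dict[int, np.ndarray] = field(default_factory=dict)
    low_t_sample: np.ndarray | None = None  # bool mask: end-of-cycle low-T frames
    coordinates: list[list[np.ndarray]] = field(default_factory=list)  # thinned
    coordinate_times_ps: list[float] = field(default_factory=list)
    aborted: bool = False


def _kinetic_temperature(velocities, masses):
    ke = 0.5 * float(np.sum(masses[:, None] * velocities**2))
    ndof = 3 * masses.size
    return 2.0 * ke / (ndof * KB_KJ_PER_MOL_K)


def run(
    frames: list[CoordinateFrame],
    terms: list[RestraintTerm],
    schedule: AnnealSchedule,
    seed: int,
    dt_ps: float = 0.01,
    friction_per_ps: float = 2.0,
    sample_stride: int = 100,
    coordinate_stride: int | None = None,
    contact_term: ContactRestraint | None = None,
    energy_abort_kj: float = 1e9,
    ramp_stride: int | None = None,
) -> TrajectoryRecord:
    """Integrate BAOAB Langevin dynamics over the annealing schedule.

    All replicas share the restraint terms (replica-averaged terms couple
    them); each replica gets its own thermostat noise stream derived from
    ``seed``, so a fixed seed reproduces the trajectory exactly.  Samples
    (time, temperatures, per-term energies, optional contact counts and
    thinned coordinates) are recorded every ``sample_stride`` steps; the
    frames falling in the final low-temperature hold of each cycle are
    flagged, since only those are meaningful for structural analysis.
    If ``ramp_stride`` is given, each term's ramp schedule is advanced one
    step every ``ramp_stride`` integrator steps.
    """
    rng = np.random.default_rng(seed)
    n_steps = int(round(schedule.total_ps / dt_ps))
    masses = [f.masses for f in frames]
    vel = []
    t0 = temperature_at(schedule, 0.0)
    for m in masses:
        sigma = np.sqrt(KB_KJ_PER_MOL_K * t0 / m)[:, None]
        vel.append(rng.standard_normal((m.size, 3)) * sigma)

    def eval_terms():
        energies = {}
        total_f = [np.zeros_like(f.positions) for f in frames]
        for term in terms:
            e, fs = term.energy_forces(frames)
            energies[term.name] = e
            for acc, fi in zip(total_f, fs):
                acc += fi
        energies["total_restraint"] = sum(
            v for k, v in energies.items() if k != "bonds"
        )
        return energies, total_f

    energies, forces = eval_terms()
    rec_t, rec_T, rec_Tk, rec_low = [], [], [], []
    rec_e: dict[str, list] = {k: [] for k in energies}
    rec_s: dict[int, list] = (
        {rid: [] for rid in contact_term.active_a} if contact_term else {}
    )
    coords: list[list[np.ndarray]] = []
    coord_times: list[float] = []
    aborted = False

    c1 = np.exp(-friction_per_ps * dt_ps)
    c2 = np.sqrt(1.0 - c1 * c1)
    low_t_start = schedule.cycle_ps - schedule.hold_low_ps

    for step in range(n_steps):
        time = step * dt_ps
        if ramp_stride is not None:
            for term in terms:
                term.set_ramp_step(step // ramp_stride)
        temp = temperature_at(schedule, time)
        # B
        for v, f, m in zip(vel, forces, masses):
            v += 0.5 * dt_ps * f / m[:, None]
        # A
        for frame, v in zip(frames, vel):
            frame.positions += 0.5 * dt_ps * v
        # O
        for v, m in zip(vel, masses):
            sigma = np.sqrt(KB_KJ_PER_MOL_K * temp / m)[:, None]
            v *= c1
            v += c2 * sigma * rng.standard_normal(v.shape)
        # A
        for frame, v in zip(frames, vel):
            frame.positions += 0.5 * dt_ps * v
        energies, forces = eval_terms()
        # B
        for v, f, m in zip(vel, forces, masses):
            v += 0.5 * dt_ps * f / m[:, None]

        if not np.isfinite(energies["total_restraint"]) or energies[
            "total_restraint"
        ] > energy_abort_kj:
            aborted = True
            break

        if (step + 1) % sample_stride == 0:
            t_now = (step + 1) * dt_ps
            rec_t.append(t_now)
            rec_T.append(temperature_at(schedule, t_now))
            rec_Tk.append(
                np.mean([_kinetic_temperature(v, m) for v, m in zip(vel, masses)])
            )
            for k, v in energies.items():
                rec_e[k].append(v)
            in_cycle = t_now % schedule.cycle_ps
            rec_low.append(in_cycle > low_t_start or in_cycle == 0.0)
            if contact_term is not None:
                for rid in contact_term.active_a:
                    rec_s[rid].append(
                        max(contact_count(f, contact_term, rid) for f in frames)
                    )
            if coordinate_stride is not None and (step + 1) % coordinate_stride == 0:
                coords.append([f.positions.copy() for f in frames])
                coord_times.append(t_now)

    return TrajectoryRecord(
        times_ps=np.array(rec_t),
        target_temp_K=np.array(rec_T),
        kinetic_temp_K=np.array(rec_Tk),
        energies={k: np.array(v) for k, v in rec_e.items()},
        contact_counts={k: np.array(v) for k, v in rec_s.items()},
        low_t_sample=np.array(rec_low, dtype=bool),
        coordinates=coords,
        coordinate_times_ps=coord_times,
        aborted=aborted,
    )


def swap_analysis(
    traj: TrajectoryRecord,
    schedule: AnnealSchedule,
    residue_a: int,
    residue_b: int,
    threshold: float = 1.0,
) -> dict:
    """Per-cycle pocket occupancy of two competing anchor residues.

    A residue 'occupies the pocket' in a cycle if its recorded contact
    count meets ``threshold`` at the last low-temperature sample of that
    cycle.  Reports the occupancy traces and the hand-off cycles: the
    cycle at which residue A last left the pocket and residue B first
    entered (None when no transition happened).
    """
    for rid in (residue_a, residue_b):
        if rid not in traj.contact_counts:
            raise ValueError(f"no contact record for residue {rid}")
    n_cycles = int(np.floor(traj.times_ps[-1] / schedule.cycle_ps)) if traj.times_ps.size else 0
    occ = {residue_a: [], residue_b: []}
    for c in range(n_cycles):
        end = (c + 1) * schedule.cycle_ps
        mask = (traj.times_ps <= end + 1e-9) & traj.low_t_sample
        if not mask.any():
            for rid in occ:
                occ[rid].append(False)
            continue
        idx = np.where(mask)[0][-1]
        for rid in occ:
            occ[rid].append(bool(traj.contact_counts[rid][idx] >= threshold))
    occ_a = np.array(occ[residue_a], dtype=bool)
    occ_b = np.array(occ[residue_b], dtype=bool)

    def first_true(x):
        w = np.where(x)[0]
        return int(w[0]) if w.size else None

    left_a = None
    if occ_a.size and occ_a[0]:
        w = np.where(~occ_a)[0]
        left_a = int(w[0]) if w.size else None
    return {
        "occupancy_a": occ_a,
        "occupancy_b": occ_b,
        "a_leaves_cycle": left_a,
        "b_enters_cycle": first_true(occ_b),
    }
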