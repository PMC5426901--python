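"""Replica-averaged restraint potentials with analytic gradients.

Four families of experimental restraints steer a structural ensemble of M
simultaneously simulated replicas toward agreement with NMR and
mutagenesis data:

* a flat-bottomed centre-of-mass wall,  E = k (d - d_max)^2  for d > d_max,
  pulling two groups of "active" residues within a maximum distance;
* NOE distance restraints, quadratic in the deviation from model
  distances, with the replica-averaged effective distance
  d_eff = ( (1/M) sum_m r_m^-6 )^(-1/6)  (slow-exchange r^-6 averaging);
* chemical-shift restraints, quadratic in the deviation of the
  replica-mean back-calculated shift from the measured one, with the
  back-calculation delegated to a pluggable predictor;
* contact-number restraints: for each active residue i the number of
  contacts S_i to the partner's active residues is pushed above 1 in at
  least one replica, via a one-sided quadratic on a smooth max over
  replicas.

All force constants enter through ramp schedules that raise them stepwise
from zero, letting the system relax as each restraint is switched on.
Internal units: nm, kJ/mol; forces in kJ/(mol nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
from scipy.special import logsumexp, softmax

__all__ = [
    "CoordinateFrame",
    "WallRestraint",
    "NOERestraintSet",
    "CSRestraintSet",
    "ContactRestraint",
    "RampSchedule",
    "ShiftPredictor",
    "LinearToyPredictor",
    "wall_energy",
    "noe_energy",
    "cs_energy",
    "contact_count",
    "contact_restraint_energy",
    "apply_ramp",
]

CS_NUCLEI = ("CA", "C", "HA", "HN", "N")


@dataclass
class CoordinateFrame:
    """Coordinates (nm) and topology of one replica of a bead/atom system."""

    positions: np.ndarray  # (N, 3) nm
    masses: np.ndarray  # (N,) amu
    residues: dict[int, np.ndarray] = field(default_factory=dict)  # id -> atom idx
    replica_index: int = 0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if self.masses.shape != (self.positions.shape[0],):
            raise ValueError("masses must have shape (N,)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        n = self.positions.shape[0]
        self.residues = {
            int(k): np.asarray(v, dtype=int) for k, v in self.residues.items()
        }
        for rid, idx in self.residues.items():
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ValueError(f"residue {rid} references invalid atom indices")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def com(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices, dtype=int)
        if idx.size == 0:
            raise ValueError("empty atom group")
        m = self.masses[idx]
        return (self.positions[idx] * m[:, None]).sum(axis=0) / m.sum()


# --------------------------------------------------------------------------
# wall restraint (centre-of-mass flat-bottom)

@dataclass
class WallRestraint:
    k: float  # kJ/(mol nm^2)
    d_max_nm: float
    group_a: np.ndarray  # atom indices
    group_b: np.ndarray

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("k must be non-negative")
        if self.d_max_nm <= 0:
            raise ValueError("d_max must be positive")
        self.group_a = np.asarray(self.group_a, dtype=int)
        self.group_b = np.asarray(self.group_b, dtype=int)
        if self.group_a.size == 0 or self.group_b.size == 0:
            raise ValueError("wall groups must be non-empty")
        if np.intersect1d(self.group_a, self.group_b).size:
            raise ValueError("wall groups must be disjoint")


def wall_energy(frame: CoordinateFrame, r: WallRestraint):
    """Flat-bottomed quadratic wall on the mass-weighted COM separation.

    Returns ``(energy, forces)`` with forces shaped like ``positions``.
    """
    com_a = frame.com(r.group_a)
    com_b = frame.com(r.group_b)
    dvec = com_a - com_b
    d = float(np.linalg.norm(dvec))
    forces = np.zeros_like(frame.positions)
    if d <= r.d_max_nm or d == 0.0:
        return 0.0, forces
    energy = r.k * (d - r.d_max_nm) ** 2
    # dE/d(com_a) = 2k(d-dmax) * unit vector; distribute by mass fraction
    g = 2.0 * r.k * (d - r.d_max_nm) * dvec / d
    ma = frame.masses[r.group_a]
    mb = frame.masses[r.group_b]
    forces[r.group_a] -= np.outer(ma / ma.sum(), g)
    forces[r.group_b] += np.outer(mb / mb.sum(), g)
    return float(energy), forces


# --------------------------------------------------------------------------
# NOE restraints with r^-6 replica averaging

@dataclass
class NOERestraintSet:
    pairs: list[tuple[int, int, float]]  # (atom_i, atom_j, d_model nm)
    beta: float = 0.25  # kJ/(mol nm^2)
    replica_averaged: bool = True

    def __post_init__(self):
        seen = set()
        for i, j, d in self.pairs:
            if d <= 0:
                raise ValueError(f"model distance must be positive for pair ({i},{j})")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate NOE pair {key}")
            seen.add(key)


def _pair_distances(frames: list[CoordinateFrame], pairs):
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    vec = np.stack([f.positions[ii] - f.positions[jj] for f in frames])  # (M,P,3)
    r = np.linalg.norm(vec, axis=2)  # (M, P)
    return ii, jj, vec, r


def noe_energy(frames: list[CoordinateFrame], r: NOERestraintSet):
    """NOE restraint energy and per-replica forces.

    In replica mode the effective distance per pair is
    (mean_m r_m^-6)^(-1/6); with a single replica (or
    ``replica_averaged=False``) this reduces exactly to the per-frame
    quadratic sum over pairs.
    """
    if not frames:
        raise ValueError("need at least one replica")
    M = len(frames)
    d_model = np.array([p[2] for p in r.pairs])
    ii, jj, vec, dist = _pair_distances(frames, r.pairs)
    if np.any(dist == 0):
        raise ValueError("coincident atoms in an NOE pair")
    forces = [np.zeros_like(f.positions) for f in frames]

    if r.replica_averaged:
        inv6 = dist**-6  # (M, P)
        mean6 = inv6.mean(axis=0)  # (P,)
        d_eff = mean6 ** (-1.0 / 6.0)
        dev = d_model - d_eff
        energy = r.beta * float(np.sum(dev**2))
        # dE/dd_eff = -2 beta dev ; dd_eff/dr_m = d_eff^7 r_m^-7 / M
        coef = -2.0 * r.beta * dev * d_eff**7 / M  # (P,)
        for m in range(M):
            # dE/dx_i = coef * r_m^-7 * (x_i - x_j)/r_m
            w = coef * dist[m] ** -8  # includes 1/r for the unit vector
            contrib = (w[:, None]) * vec[m]
            np.add.at(forces[m], ii, -contrib)
            np.add.at(forces[m], jj, contrib)
    else:
        dev = d_model[None, :] - dist  # (M, P)
        energy = r.beta * float(np.sum(dev**2))
        for m in range(M):
            w = -2.0 * r.beta * dev[m] / dist[m]
            contrib = (w[:, None]) * vec[m]
            np.add.at(forces[m], ii, -contrib)
            np.add.at(forces[m], jj, contrib)
    return energy, forces


# --------------------------------------------------------------------------
# chemical-shift restraints with a pluggable predictor

class ShiftPredictor(Protocol):
    """Back-calculates shifts and their coordinate gradients for a frame.

    ``predict`` returns ``{(residue, nucleus): (shift_ppm, grad)}`` with
    ``grad`` shaped (N, 3) in ppm/nm.
    """

    def predict(self, frame: CoordinateFrame) -> dict[tuple[int, str], tuple[float, np.ndarray]]:
        ...


@dataclass
class LinearToyPredictor:
    """Exactly linear shift model for testing the restraint machinery:
    shift(k,l) = base + sum_n w_n . x_n over all bead coordinates.

    Not a physical predictor; a stand-in with analytically trivial
    gradients so the restraint chain rule can be validated in isolation.
    """

    terms: dict[tuple[int, str], tuple[float, np.ndarray]]  # (base, weights (N,3))

    def predict(self, frame: CoordinateFrame):
        out = {}
        for key, (base, w) in self.terms.items():
            out[key] = (base + float(np.sum(w * frame.positions)), w)
        return out


@dataclass
class CSRestraintSet:
    targets: list[tuple[int, str, float]]  # (residue, nucleus, delta_exp ppm)
    alpha: float  # kJ/(mol ppm^2)
    predictor: ShiftPredictor

    def __post_init__(self):
        for res, nuc, _ in self.targets:
            if nuc not in CS_NUCLEI:
                raise ValueError(f"nucleus {nuc!r} not in {CS_NUCLEI}")


def cs_energy(frames: list[CoordinateFrame], r: CSRestraintSet):
    """Chemical-shift restraint on the replica-mean predicted shifts."""
    if not frames:
        raise ValueError("need at least one replica")
    M = len(frames)
    preds = [r.predictor.predict(f) for f in frames]
    forces = [np.zeros_like(f.positions) for f in frames]
    energy = 0.0
    for res, nuc, d_exp in r.targets:
        key = (res, nuc)
        for m, p in enumerate(preds):
            if key not in p:
                raise ValueError(
                    f"predictor provides no shift for residue {res} nucleus {nuc} "
                    f"(replica {m})"
                )
        mean = sum(p[key][0] for p in preds) / M
        dev = d_exp - mean
        energy += r.alpha * dev * dev
        coef = -2.0 * r.alpha * dev / M  # dE/d(delta_m^calc)
        for m, p in enumerate(preds):
            forces[m] -= coef * p[key][1]
    return float(energy), forces


# --------------------------------------------------------------------------
# contact-number restraints

@dataclass
class ContactRestraint:
    active_a: list[int]  # residue ids on the reader side
    active_b: list[int]  # residue ids on the nucleosome side
    r0_nm: float = 0.65  # switching distance; 1.0 nm in the second variant
    k: float = 50.0  # kJ/(mol nm^2)
    smooth: bool = False
    sharpness: float = 10.0  # soft-max temperature over replicas

    def __post_init__(self):
        if not self.active_a or not self.active_b:
            raise ValueError("active residue sets must be non-empty")
        if self.r0_nm <= 0:
            raise ValueError("switching distance must be positive")


def _switch(x: np.ndarray):
    """Rational switching (1-(r/r0)^6)/(1-(r/r0)^12) == 1/(1+(r/r0)^6),
    value and derivative w.r.t. x = r/r0. Continuous 0.5 at x=1."""
    x6 = x**6
    s = 1.0 / (1.0 + x6)
    ds = -6.0 * x**5 * s * s
    return s, ds


def _min_pair(frame: CoordinateFrame, res_i: int, res_j: int):
    ai = frame.residues[res_i]
    aj = frame.residues[res_j]
    diff = frame.positions[ai][:, None, :] - frame.positions[aj][None, :, :]
    d = np.linalg.norm(diff, axis=2)
    flat = np.argmin(d)
    u, v = np.unravel_index(flat, d.shape)
    return float(d[u, v]), int(ai[u]), int(aj[v])


def contact_count(frame: CoordinateFrame, r: ContactRestraint, residue_i: int):
    """Number of contacts S_i of one active reader residue.

    Binary mode: s_ij = 1 iff any atom pair of residues i, j is closer
    than r0.  Smooth mode: the rational switching function evaluated on
    the minimum inter-atom distance, giving s_ij in (0, 1) with value 0.5
    exactly at r0.
    """
    if residue_i not in r.active_a:
        raise ValueError(f"residue {residue_i} is not in the active reader set")
    total = 0.0
    for res_j in r.active_b:
        d, _, _ = _min_pair(frame, residue_i, res_j)
        if r.smooth:
            s, _ = _switch(d / r.r0_nm)
            total += s
        else:
            total += 1.0 if d < r.r0_nm else 0.0
    return total


def contact_restraint_energy(frames: list[CoordinateFrame], r: ContactRestraint):
    """'At least one replica in contact' penalty.

    For each active reader residue i the smooth contact count S~_im is
    computed per replica; the replica aggregate uses the log-sum-exp soft
    max  S*_i = (1/kappa) log sum_m exp(kappa S~_im),  which is >= max_m
    S~_im, so the penalty  k (1 - S*_i)^2 (applied only when S*_i < 1)
    vanishes whenever any single replica satisfies S~_i >= 1.  Forces
    follow the softmax weights over replicas by the chain rule.
    """
    if not frames:
        raise ValueError("need at least one replica")
    M = len(frames)
    kappa = r.sharpness
    energy = 0.0
    forces = [np.zeros_like(f.positions) for f in frames]
    for res_i in r.active_a:
        s_rep = np.zeros(M)
        # per (replica, partner) bookkeeping for the chain rule
        grads: list[list[tuple[int, int, np.ndarray]]] = [[] for _ in range(M)]
        for m, frame in enumerate(frames):
            for res_j in r.active_b:
                d, ai, aj = _min_pair(frame, res_i, res_j)
                s, ds = _switch(d / r.r0_nm)
                s_rep[m] += s
                # d s / d x_ai = ds/dx * (1/r0) * unit(ai - aj)
                unit = (frame.positions[ai] - frame.positions[aj]) / d
                grads[m].append((ai, aj, (ds / r.r0_nm) * unit))
        s_soft = float(logsumexp(kappa * s_rep) / kappa)
        if s_soft >= 1.0:
            continue
        dev = 1.0 - s_soft
        energy += r.k * dev * dev
        weights = softmax(kappa * s_rep)
        coef = -2.0 * r.k * dev  # dE/dS*
        for m in range(M):
            for ai, aj, g in grads[m]:
                f = coef * weights[m] * g
                forces[m][ai] -= f
                forces[m][aj] += f
    return float(energy), forces


def binary_contact_satisfied(frames: list[CoordinateFrame], r: ContactRestraint) -> dict[int, bool]:
    """Reporting helper: per active reader residue, is S_i >= 1 (binary
    counting) in at least one replica?"""
    hard = ContactRestraint(
        r.active_a, r.active_b, r.r0_nm, r.k, smooth=False, sharpness=r.sharpness
    )
    out = {}
    for res_i in r.active_a:
        out[res_i] = any(
            contact_count(f, hard, res_i) >= 1.0 for f in frames
        )
    return out


# --------------------------------------------------------------------------
# force-constant ramps

@dataclass(frozen=True)
class RampSchedule:
    """Stepwise-increasing force constant: value(i) = start + i*step,
    clamped at stop.  ``step`` must divide (stop - start)."""

    name: str
    start: float
    stop: float
    step: float
    units: str = ""

    def __post_init__(self):
        if self.step <= 0 or self.stop < self.start:
            raise ValueError("need stop >= start and step > 0")
        n = (self.stop - self.start) / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("step must divide (stop - start)")

    @property
    def n_steps(self) -> int:
        return int(round((self.stop - self.start) / self.step))


def apply_ramp(schedule: RampSchedule, step_index: int) -> float:
    if step_index < 0:
        raise ValueError("step index must be non-negative")
    return min(schedule.start + step_index * schedule.step, schedule.stop)


#: the published ramp endpoints for the three restraint force constants
DEFAULT_RAMPS = {
    "alpha_cs": RampSchedule("alpha_cs", 0.0, 24.0, 1.0, "kJ/(mol ppm^2)"),
    "beta_noe": RampSchedule("beta_noe", 0.0, 2.0, 0.1, "kJ/(mol nm^2)"),
    "k_contact": RampSchedule("k_contact", 0.0, 50.0, 1.0, "kJ/(mol nm^2)"),
}

#: active-residue membership used for the contact restraints: reader side
#: (RNF169 LRM2) and nucleosome side (H2A/H2B), by residue number.
ACTIVE_RESIDUES_READER = (689, 697, 699, 700, 701)
ACTIVE_RESIDUES_NCP_H2A = (50, 57, 60, 63, 64, 89, 91)
ACTIVE_RESIDUES_NCP_H2B = (45, 99, 103)
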