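"""Exercise the replica-averaged restraint potentials on a seeded bead
fixture: term-by-term energies, the single-replica reduction of the NOE
average, and the published force-constant ramps."""

from pathlib import Path

import numpy as np

from ubnmr import io
from ubnmr.restraints import (
    ContactRestraint,
    CSRestraintSet,
    DEFAULT_RAMPS,
    LinearToyPredictor,
    NOERestraintSet,
    WallRestraint,
    apply_ramp,
    contact_restraint_energy,
    cs_energy,
    noe_energy,
    wall_energy,
)
from ubnmr.synthetic import SyntheticConfig, generate_bead_system

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    frames, (ga, gb), dists = generate_bead_system(
        SyntheticConfig(seed=11), 20, (list(range(5)), list(range(10, 15))),
        n_replicas=4,
    )
    out = {}

    wall = WallRestraint(k=20.0, d_max_nm=2.5, group_a=ga, group_b=gb)
    out["wall_kj_mol"], _ = wall_energy(frames[0], wall)

    pairs = [(i, j, d * 0.85) for i, j, d in dists]
    out["noe_replica_kj_mol"], _ = noe_energy(frames, NOERestraintSet(pairs, beta=0.25))
    e1, _ = noe_energy(frames[:1], NOERestraintSet(pairs, beta=0.25))
    e1_direct, _ = noe_energy(
        frames[:1], NOERestraintSet(pairs, beta=0.25, replica_averaged=False)
    )
    out["noe_single_replica_reduction_gap"] = abs(e1 - e1_direct)

    rng = np.random.default_rng(1)
    terms = {
        (k, l): (float(rng.normal()), rng.normal(size=(20, 3)) * 0.1)
        for k in range(1, 4) for l in ("CA", "C", "HA", "HN", "N")
    }
    targets = [(k, l, float(rng.normal(0.0, 0.3))) for (k, l) in terms]
    out["cs_kj_mol"], _ = cs_energy(
        frames, CSRestraintSet(targets, alpha=24.0, predictor=LinearToyPredictor(terms))
    )

    contact = ContactRestraint(
        active_a=list(ga), active_b=list(gb), r0_nm=0.65, k=50.0, smooth=True
    )
    out["contact_kj_mol"], _ = contact_restraint_energy(frames, contact)

    out["ramps"] = {
        name: {
            "stop": sched.stop,
            "n_steps": sched.n_steps,
            "final_value": apply_ramp(sched, sched.n_steps),
            "units": sched.units,
        }
        for name, sched in DEFAULT_RAMPS.items()
    }

    for key, val in out.items():
        print(f"{key}: {val}")
    io.write_json(ROOT / "restraint_energies.json", out)


if __name__ == "__main__":
    main()
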