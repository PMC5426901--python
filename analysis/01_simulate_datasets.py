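"""Generate every synthetic dataset the downstream analyses consume.

Writes CSV measurement tables with JSON truth sidecars under
results/data/: fast-exchange titrations at the nucleosome-bound (24 µM)
and free-ubiquitin (956 µM) affinities, intermediate-exchange 13C traces,
a gradient diffusion decay, and triple-quantum buildup ensembles for the
free and reader-bound states.
"""

from pathlib import Path

import numpy as np

from ubnmr import io
from ubnmr.isotherm import ncp_site_concentration
from ubnmr.lineshape import ExchangeModel
from ubnmr.synthetic import (
    SyntheticConfig,
    generate_buildup_series,
    generate_diffusion_series,
    generate_lineshape_series,
    generate_titration,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 20170413

def main():
    OUT.mkdir(parents=True, exist_ok=True)

    # titrations: two sites per particle at 50 µM nucleosome
    sites = ncp_site_concentration(50.0)
    tight = generate_titration(
        SyntheticConfig(seed=SEED, noise_sd=0.02, true_params={"kd_uM": 24.0}),
        np.linspace(0, 2.6, 16), sites,
    )
    io.write_titration(OUT / "titration_ncp.csv", tight)
    weak = generate_titration(
        SyntheticConfig(seed=SEED + 1, noise_sd=0.02, true_params={"kd_uM": 956.0}),
        np.linspace(0, 42, 10), 50.0,
    )
    io.write_titration(OUT / "titration_free_ub.csv", weak)
    print(f"titrations: {tight.n_points} + {weak.n_points} points -> {OUT}")

    # intermediate-exchange 13C traces across the titration
    model = ExchangeModel(
        shift_free=0.5, shift_bound=1.2, r2_free=40.0, r2_bound=80.0,
        kon=2.4e7, kd=24.0, spectrometer_freq=150.9,
    )
    traces, truth = generate_lineshape_series(
        SyntheticConfig(seed=SEED + 2, noise_sd=0.01), model,
        [0.25, 0.5, 0.9, 1.4, 2.0], 100.0,
    )
    for n, (freq, inten, lt, pt) in enumerate(traces):
        io.write_trace(OUT / f"trace_{n}.csv", freq, inten, lt, pt)
    io.write_json(OUT / "traces.truth.json", truth)
    print(f"lineshapes: {len(traces)} traces at kon={truth['kon_M_s']:.2e}")

    # diffusion decay of the ~250 kDa particle
    decay = generate_diffusion_series(
        SyntheticConfig(seed=SEED + 3, noise_sd=0.01), np.linspace(2, 48, 12), 0.2
    )
    io.write_decay(OUT / "diffusion_ncp.csv", decay)
    print(f"diffusion: D_true={decay.meta['truth']['d_cm2_s']:.2e} cm^2/s")

    # methyl buildup ensembles: bound state twice as rigid as free
    rng = np.random.default_rng(SEED + 4)
    base = rng.uniform(18.0, 32.0, size=20)
    for state, values, off in (("free", base, 100), ("bound", 2.0 * base, 200)):
        for i, v in enumerate(values):
            series = generate_buildup_series(
                SyntheticConfig(seed=SEED + off + i, noise_sd=0.02),
                s2tc_ns=float(v), residue=f"m{i:02d}",
            )
            io.write_buildup(OUT / f"buildup_{state}_{i:02d}.csv", series)
    print("buildups: 2 x 20 methyl probes (free / bound)")


if __name__ == "__main__":
    main()
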