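"""Fit the translational diffusion constant of the ubiquitylated
nucleosome from its gradient decay and place it next to reference
particles measured under identical conditions."""

from pathlib import Path

from ubnmr import io
from ubnmr.diffusion import compare_species, fit_diffusion

ROOT = Path(__file__).resolve().parents[1] / "results"

#: literature diffusion constant of the 180 kDa heptameric proteasome
#: alpha-ring under matching conditions, for scale
QUARTER_PROTEASOME_D = 4.2e-7


def main():
    series = io.read_decay(ROOT / "data" / "diffusion_ncp.csv")
    fit = fit_diffusion(series)
    truth = series.meta["truth"]["d_cm2_s"]
    print(
        f"D = {fit.d_cm2_s:.2e} cm^2/s (generated at {truth:.2e}); "
        f"linearized cross-check {fit.d_linearized:.2e}"
    )
    table = compare_species(
        [("ubiquitylated-NCP", fit.d_cm2_s), ("quarter-proteasome", QUARTER_PROTEASOME_D)],
        reference="quarter-proteasome",
    )
    for row in table:
        print(f"  {row['label']}: {row['d_cm2_s']:.2e} ({row['ratio_to_ref']:.2f}x ref)")
    io.write_json(
        ROOT / "diffusion_fit.json",
        {"d_cm2_s": fit.d_cm2_s, "d_sd": fit.d_sd, "d_true": truth, "comparison": table},
    )


if __name__ == "__main__":
    main()
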