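"""Weighted methyl chemical-shift perturbations and significance flagging.

The combined perturbation for a methyl probe i between free and bound
spectra is

    CSP_i = sqrt( ddH_i^2 + ddC_i^2 * w_i )      [ppm]

where ddH/ddC are the 1H/13C shift differences and the per-methyl-type
weight w_i = sigma_H,i / sigma_C,i scales the (wider) carbon dimension onto
the proton scale using the BMRB dispersion of deposited methyl shifts.
Residues whose CSP exceeds the set mean by more than one standard
deviation are flagged as significantly perturbed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PeakAssignment",
    "CSPRecord",
    "DEFAULT_SIGMA_TABLE",
    "compute_weights",
    "compute_csp",
    "flag_significant",
]

#: ILV methyl vocabulary. Leu/Val without stereospecific assignment use the
#: upfield/downfield "a"/"b" convention.
METHYL_LABELS = frozenset(
    {
        "Ile-d1",
        "Leu-d1", "Leu-d2", "Leu-a", "Leu-b",
        "Val-g1", "Val-g2", "Val-a", "Val-b",
    }
)

#: BMRB-derived standard deviations of deposited ILV methyl shifts
#: (sigma_H, sigma_C in ppm per methyl type). Ratios fall in ~0.16-0.18.
DEFAULT_SIGMA_TABLE: dict[str, tuple[float, float]] = {
    "Ile-d1": (0.29, 1.70),
    "Leu": (0.26, 1.55),
    "Val": (0.27, 1.60),
}


@dataclass(frozen=True)
class PeakAssignment:
    residue_id: int
    atom_label: str
    h_shift: float  # ppm
    c_shift: float  # ppm

    def __post_init__(self):
        if self.atom_label not in METHYL_LABELS:
            raise ValueError(f"unknown methyl label {self.atom_label!r}")
        if not (np.isfinite(self.h_shift) and np.isfinite(self.c_shift)):
            raise ValueError(
                f"non-finite shift for residue {self.residue_id} {self.atom_label}"
            )

    @property
    def key(self) -> tuple[int, str]:
        return (self.residue_id, self.atom_label)


@dataclass
class CSPRecord:
    residue_id: int
    atom_label: str
    delta_h: float
    delta_c: float
    weight: float
    csp: float
    significant: bool = False


def compute_weights(sigma_table: dict[str, tuple[float, float]] | None = None) -> dict[str, float]:
    """Per-methyl-type weights w = sigma_H / sigma_C.

    ``sigma_table`` maps a methyl type (or full label) to (sigma_H, sigma_C)
    in ppm; defaults to the bundled BMRB-derived table.
    """
    table = DEFAULT_SIGMA_TABLE if sigma_table is None else sigma_table
    weights = {}
    for key, (sh, sc) in table.items():
        if sh <= 0 or sc <= 0:
            raise ValueError(f"sigma values must be positive for {key!r}")
        weights[key] = sh / sc
    return weights


def _weight_for(label: str, weights: dict[str, float]) -> float:
    if label in weights:
        return weights[label]
    base = label.split("-")[0]
    if base in weights:
        return weights[base]
    raise KeyError(f"no weight for methyl label {label!r}")


def compute_csp(
    free: list[PeakAssignment],
    bound: list[PeakAssignment],
    weights: dict[str, float] | None = None,
) -> tuple[list[CSPRecord], list[tuple[int, str]]]:
    """Combine matched free/bound peak lists into weighted CSPs.

    Peaks are matched on (residue_id, atom_label); unmatched keys are
    returned (second element) rather than silently dropped.  Records come
    back sorted by residue id then label.
    """
    weights = compute_weights() if weights is None else weights

    def index(peaks, name):
        out = {}
        for p in peaks:
            if p.key in out:
                raise ValueError(f"duplicate peak key {p.key} in {name} list")
            out[p.key] = p
        return out

    fmap, bmap = index(free, "free"), index(bound, "bound")
    common = sorted(fmap.keys() & bmap.keys())
    unmatched = sorted((fmap.keys() | bmap.keys()) - set(common))
    records = []
    for key in common:
        pf, pb = fmap[key], bmap[key]
        dh = pb.h_shift - pf.h_shift
        dc = pb.c_shift - pf.c_shift
        w = _weight_for(pf.atom_label, weights)
        records.append(
            CSPRecord(
                residue_id=pf.residue_id,
                atom_label=pf.atom_label,
                delta_h=dh,
                delta_c=dc,
                weight=w,
                csp=float(np.sqrt(dh * dh + dc * dc * w)),
            )
        )
    return records, unmatched


def pair_unassigned(peaks: list[PeakAssignment]) -> list[PeakAssignment]:
    """Map stereo-unassigned Leu/Val methyl pairs onto "a"/"b" labels by
    sorted 1H shift within a residue: "a" upfield (smaller ppm), "b"
    downfield. Peaks already carrying a/b or stereo labels pass through."""
    by_res: dict[tuple[int, str], list[PeakAssignment]] = {}
    out = []
    for p in peaks:
        base = p.atom_label.split("-")[0]
        if base in ("Leu", "Val") and p.atom_label.endswith(("1", "2")):
            by_res.setdefault((p.residue_id, base), []).append(p)
        else:
            out.append(p)
    for (rid, base), pair in by_res.items():
        pair = sorted(pair, key=lambda p: p.h_shift)
        for p, tag in zip(pair, ("a", "b")):
            out.append(PeakAssignment(rid, f"{base}-{tag}", p.h_shift, p.c_shift))
    return sorted(out, key=lambda p: p.key)


def flag_significant(
    records: list[CSPRecord], n_sigma: float = 1.0, ddof: int = 1
) -> tuple[list[CSPRecord], float, float]:
    """Flag records with CSP strictly above mean + n_sigma * sd.

    The sample (ddof=1) standard deviation is used by default.  Returns the
    updated records plus the mean and sd actually used.  Requires at least
    three records for the spread to be meaningful.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 CSP records to define a 1-sigma rule")
    vals = np.array([r.csp for r in records])
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=ddof))
    thresh = mean + n_sigma * sd
    for r in records:
        r.significant = bool(r.csp > thresh)
    return records, mean, sd
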