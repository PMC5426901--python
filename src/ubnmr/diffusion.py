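"""Translational diffusion from pulsed-field-gradient intensity decays.

Gradient-encoded 1-D intensities decay mono-exponentially in the squared
gradient strength,

    I(G) = I0 * exp(-a * D * G^2)

with D the translational diffusion constant (cm^2/s), G the encoding
gradient (gauss/cm) and ``a`` a composite of pulse-sequence parameters
(gradient shape factors, encoding length and diffusion delay; units
s cm^-2 gauss^-2 relative to the above).  ``a`` is an experimental input,
never computed here: the encoding scheme's shape factors belong to the
pulse sequence, not to the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["DecaySeries", "DiffusionFit", "fit_diffusion", "compare_species"]


@dataclass
class DecaySeries:
    """Generic (x, intensity) decay/buildup container.

    ``x_role`` tags the abscissa: "gradient" (gauss/cm) for diffusion
    decays, "delay" (s) for relaxation series.
    """

    x: np.ndarray
    intensity: np.ndarray
    x_role: str = "gradient"
    i0: float | None = None
    diffusion_time_s: float | None = None
    a_constant: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.x.shape != self.intensity.shape:
            raise ValueError("x and intensity length mismatch")
        if np.any(self.x < 0):
            raise ValueError("x values must be non-negative")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")


@dataclass
class DiffusionFit:
    d_cm2_s: float
    d_sd: float
    i0: float
    d_linearized: float
    warnings: list[str] = field(default_factory=list)


def fit_diffusion(series: DecaySeries) -> DiffusionFit:
    """Fit D by nonlinear least squares on I = I0 exp(-a D G^2).

    A log-linear (slope of ln I vs G^2) estimate is reported alongside for
    cross-checking; on noiseless data the two agree to numerical precision.
    """
    if series.a_constant is None:
        raise ValueError("a_constant (experimental composite) is required")
    if series.x.size < 4:
        raise ValueError("need at least 4 gradient points")
    g2 = series.x**2
    if np.ptp(g2) == 0:
        raise ValueError("gradient strengths are all equal: no decay information")
    if np.any(series.intensity <= 0):
        raise ValueError("intensities must be positive for a log-domain cross-check")
    a = series.a_constant
    notes = []
    order = np.argsort(g2)
    if np.any(np.diff(series.intensity[order]) > 0):
        notes.append("non-monotone decay with increasing G^2 (noise or artifact)")

    # linearised estimate: ln I = ln I0 - a D G^2
    slope, intercept = np.polyfit(g2, np.log(series.intensity), 1)
    d_lin = -slope / a

    def model(g2, i0, d):
        return i0 * np.exp(-a * d * g2)

    p0 = [float(np.exp(intercept)), max(d_lin, 1e-12)]
    popt, pcov = curve_fit(model, g2, series.intensity, p0=p0, maxfev=10000)
    d_sd = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan
    for note in notes:
        warnings.warn(note, stacklevel=2)
    return DiffusionFit(
        d_cm2_s=float(popt[1]),
        d_sd=d_sd,
        i0=float(popt[0]),
        d_linearized=float(d_lin),
        warnings=notes,
    )


def compare_species(
    fits: list[tuple[str, float]], reference: str | None = None
) -> list[dict]:
    """Tabulate diffusion constants with ratios to a reference species.

    ``fits`` is a list of (label, D) pairs; ``reference`` defaults to the
    first label.  Rows are sorted by D descending with ties kept in input
    order (stable sort), each row carrying D and D/D_ref.
    """
    if len(fits) < 1:
        raise ValueError("need at least one fit")
    ref_label = reference if reference is not None else fits[0][0]
    d_ref = dict(fits).get(ref_label)
    if d_ref is None:
        raise ValueError(f"reference {ref_label!r} not among fits")
    rows = sorted(fits, key=lambda t: -t[1])
    return [
        {"label": lab, "d_cm2_s": d, "ratio_to_ref": d / d_ref, "reference": ref_label}
        for lab, d in rows
    ]
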