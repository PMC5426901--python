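"""Equilibrium 1:1 binding analysis from fast-exchange NMR titrations.

For a receptor P (the isotope-labelled, observed species) titrated with a
ligand L, the fast-exchange chemical-shift change of a receptor resonance is

    ddelta' = ddelta_max' * f_b([L]_T, [P]_T, K_d)

with the exact (ligand-depletion-aware) bound fraction from the quadratic
root of the 1:1 mass-action equations:

    f_b = ( [L]T + [P]T + Kd - sqrt(([L]T + [P]T + Kd)^2 - 4 [P]T [L]T) )
          / (2 [P]T)

Concentrations and K_d share units (µM throughout this package).  A
nucleosome carrying one ubiquitin on each H2A copy presents two independent
ligand-binding sites, so the site concentration entering the isotherm is
twice the particle concentration (see :func:`ncp_site_concentration`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "bound_fraction",
    "ncp_site_concentration",
    "TitrationSeries",
    "BindingFit",
    "fit_kd",
]


def bound_fraction(lt, pt, kd):
    """Fraction of receptor sites occupied, exact in ligand depletion.

    Parameters
    ----------
    lt, pt : array-like, µM
        Total ligand and total receptor-site concentrations.
    kd : float, µM
        Dissociation constant, must be positive.

    Returns
    -------
    ndarray or float in [0, min(1, lt/pt)].
    """
    lt = np.asarray(lt, dtype=float)
    pt = np.asarray(pt, dtype=float)
    if not np.isfinite(kd) or kd <= 0:
        raise ValueError(f"kd must be finite and positive, got {kd!r}")
    if np.any(lt < 0) or np.any(pt < 0):
        raise ValueError("concentrations must be non-negative")
    if np.any(pt == 0):
        raise ValueError("receptor concentration pt must be positive")
    b = lt + pt + kd
    disc = b * b - 4.0 * pt * lt
    # disc >= (kd)^2 > 0 analytically; clip guards rounding at saturation
    root = np.sqrt(np.clip(disc, 0.0, None))
    return (b - root) / (2.0 * pt)


def ncp_site_concentration(ncp_total_uM: float) -> float:
    """Ubiquitin-site concentration of a di-ubiquitylated nucleosome
    sample: two equivalents of ubiquitin per particle, binding assumed
    independent, so [P]_T = 2 x [NCP]."""
    if ncp_total_uM < 0:
        raise ValueError("concentration must be non-negative")
    return 2.0 * ncp_total_uM


@dataclass
class TitrationSeries:
    """Per-residue shift changes across a shared concentration schedule.

    ``shifts`` maps a residue key (e.g. "I44-d1-C") to an array of observed
    shift changes ddelta' (ppm, relative to the ligand-free point), one per
    titration point.
    """

    lt_uM: np.ndarray
    pt_uM: np.ndarray
    shifts: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lt_uM = np.asarray(self.lt_uM, dtype=float)
        self.pt_uM = np.asarray(self.pt_uM, dtype=float)
        if self.lt_uM.shape != self.pt_uM.shape:
            raise ValueError("lt and pt schedules differ in length")
        if np.any(self.lt_uM < 0) or np.any(self.pt_uM < 0):
            raise ValueError("concentrations must be non-negative")
        ratios = self.lt_uM / np.where(self.pt_uM > 0, self.pt_uM, np.nan)
        finite = ratios[np.isfinite(ratios)]
        if np.any(np.diff(finite) < 0):
            raise ValueError("titration points must be ordered by ratio")
        self.shifts = {k: np.asarray(v, dtype=float) for k, v in self.shifts.items()}
        for key, v in self.shifts.items():
            if v.shape != self.lt_uM.shape:
                raise ValueError(f"residue {key}: series length mismatch")

    @property
    def n_points(self) -> int:
        return self.lt_uM.size

    def ratios(self) -> np.ndarray:
        return self.lt_uM / self.pt_uM


@dataclass
class BindingFit:
    """Result of an isotherm fit.

    ``kd_uM`` is the reported dissociation constant; in per-residue mode it
    is the mean of individually fitted values and ``kd_sd_uM`` their sample
    standard deviation (the convention used when per-residue isotherms are
    fitted one at a time and spread across residues is quoted as the error).
    """

    kd_uM: float
    kd_sd_uM: float
    dmax_ppm: dict[str, float]
    per_residue_kd_uM: dict[str, float]
    residuals: dict[str, np.ndarray]
    mode: str
    converged: bool = True
    at_bounds: bool = False
    excluded: list[str] = field(default_factory=list)


def _fit_single_residue(lt, pt, y, kd_starts, kd_bounds):
    """2-parameter (kd, dmax) bounded fit of one residue's isotherm,
    multi-started over log-spaced kd initial values."""

    def resid(params):
        kd, dmax = params
        return dmax * bound_fraction(lt, pt, kd) - y

    scale0 = np.max(np.abs(y)) or 1.0
    best = None
    for kd0 in kd_starts:
        sol = least_squares(
            resid,
            x0=[kd0, np.sign(y[-1] if y[-1] != 0 else 1.0) * scale0],
            bounds=([kd_bounds[0], -np.inf], [kd_bounds[1], np.inf]),
        )
        if best is None or sol.cost < best.cost:
            best = sol
    return best


def fit_kd(
    series: TitrationSeries,
    fast_exchange_only: bool = False,
    fast_exchange_max_hz: float = 60.0,
    spectrometer_freq_mhz: float | None = None,
    mode: str = "per-residue",
    kd_bounds: tuple[float, float] = (1e-3, 1e6),
    n_starts: int = 7,
) -> BindingFit:
    """Extract K_d from titration curves by nonlinear least squares.

    Two modes are provided.  ``"per-residue"`` (default) fits each residue's
    curve independently for (kd, dmax) and reports the mean kd with the
    across-residue sample standard deviation as the uncertainty.
    ``"global"`` shares a single kd across residues with residue-specific
    dmax (shared thermodynamics, residue-specific endpoints).

    ``fast_exchange_only`` drops residues whose total shift change exceeds
    ``fast_exchange_max_hz`` at an explicitly supplied spectrometer
    frequency (MHz of the observed nucleus); large shift differences put a
    resonance outside the fast-exchange regime where peak positions track
    populations, so such residues bias an equilibrium-only analysis.
    """
    if series.n_points < 4:
        raise ValueError("need at least 4 titration points")
    if not series.shifts:
        raise ValueError("need at least one residue series")
    keys = list(series.shifts)
    excluded: list[str] = []
    if fast_exchange_only:
        if spectrometer_freq_mhz is None:
            raise ValueError(
                "fast-exchange filtering needs an explicit spectrometer_freq_mhz"
            )
        keep = []
        for k in keys:
            span_hz = np.max(np.abs(series.shifts[k])) * spectrometer_freq_mhz
            (keep if span_hz <= fast_exchange_max_hz else excluded).append(k)
        keys = keep
        if not keys:
            raise ValueError("fast-exchange filter removed every residue")

    kd_starts = np.geomspace(kd_bounds[0] * 10, kd_bounds[1] / 10, n_starts)
    lt, pt = series.lt_uM, series.pt_uM

    if mode == "per-residue":
        per_kd, dmax, residmap = {}, {}, {}
        ok = True
        hit = False
        for k in keys:
            sol = _fit_single_residue(lt, pt, series.shifts[k], kd_starts, kd_bounds)
            per_kd[k] = float(sol.x[0])
            dmax[k] = float(sol.x[1])
            residmap[k] = sol.fun.copy()
            ok = ok and sol.success
            hit = hit or np.isclose(sol.x[0], kd_bounds).any()
        vals = np.array(list(per_kd.values()))
        kd = float(np.mean(vals))
        kd_sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        return BindingFit(kd, kd_sd, dmax, per_kd, residmap, mode, ok, hit, excluded)

    if mode != "global":
        raise ValueError(f"unknown mode {mode!r}")

    y_all = [series.shifts[k] for k in keys]

    def resid(params):
        kd = params[0]
        out = []
        fb = bound_fraction(lt, pt, kd)
        for i, y in enumerate(y_all):
            out.append(params[1 + i] * fb - y)
        return np.concatenate(out)

    best = None
    for kd0 in kd_starts:
        x0 = [kd0] + [y[-1] if y[-1] != 0 else np.max(np.abs(y)) or 1.0 for y in y_all]
        lb = [kd_bounds[0]] + [-np.inf] * len(y_all)
        ub = [kd_bounds[1]] + [np.inf] * len(y_all)
        sol = least_squares(resid, x0=x0, bounds=(lb, ub))
        if best is None or sol.cost < best.cost:
            best = sol
    kd = float(best.x[0])
    dmax = {k: float(best.x[1 + i]) for i, k in enumerate(keys)}
    fb = bound_fraction(lt, pt, kd)
    residmap = {k: dmax[k] * fb - series.shifts[k] for k in keys}
    # uncertainty from the Jacobian (1 sd, linearised)
    try:
        _, s, _ = np.linalg.svd(best.jac, full_matrices=False)
        thresh = np.finfo(float).eps * max(best.jac.shape) * s[0]
        s = s[s > thresh]
        cov = best.jac.T @ best.jac
        dof = max(best.fun.size - best.x.size, 1)
        sigma2 = 2 * best.cost / dof
        kd_sd = float(np.sqrt(np.linalg.inv(cov)[0, 0] * sigma2))
    except np.linalg.LinAlgError:
        kd_sd = np.nan
    return BindingFit(
        kd, kd_sd, dmax, {k: kd for k in keys}, residmap, mode,
        best.success, bool(np.isclose(kd, kd_bounds).any()), excluded,
    )
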