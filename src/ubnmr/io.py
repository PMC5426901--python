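"""Readers and writers: CSV tables, JSON reports/sidecars, YAML configs,
multi-model PDB trajectories.

Conventions: comma-separated UTF-8 CSV with a mandatory header and "."
decimal; measurement tables never contain generating-truth parameters —
truth travels in a JSON sidecar next to the data file.  All writes are
atomic (temp file + rename) so a crashed run never leaves a half-written
table.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .csp import CSPRecord, PeakAssignment
from .diffusion import DecaySeries
from .isotherm import TitrationSeries
from .relaxation import BuildupSeries

__all__ = [
    "atomic_write_text",
    "write_json",
    "read_peak_list",
    "write_peak_list",
    "write_csp_table",
    "write_titration",
    "read_titration",
    "write_decay",
    "read_decay",
    "write_buildup",
    "read_buildup",
    "write_trace",
    "read_trace",
    "write_multimodel_pdb",
    "provenance",
]


def atomic_write_text(path, text: str):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.bool_):
            return bool(o)
        return super().default(o)


def write_json(path, obj):
    atomic_write_text(path, json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")


def _write_df(path, df: pd.DataFrame):
    atomic_write_text(path, df.to_csv(index=False))


def provenance(config: dict, seed: int | None = None) -> dict:
    """Machine-readable provenance block: config hash, seed, version."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, cls=_NumpyEncoder).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "package_version": __version__,
    }


# ---------------------------------------------------------------- peak lists

PEAK_COLUMNS = ["residue_id", "atom_label", "h_ppm", "c_ppm"]


def read_peak_list(path) -> list[PeakAssignment]:
    df = pd.read_csv(path)
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    peaks, seen = [], set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            h = float(row.h_ppm)
            c = float(row.c_ppm)
            if not (np.isfinite(h) and np.isfinite(c)):
                raise ValueError("non-finite shift")
            p = PeakAssignment(int(row.residue_id), str(row.atom_label), h, c)
        except (TypeError, ValueError) as err:
            raise ValueError(f"{path}: row {row_no}: {err}") from None
        if p.key in seen:
            raise ValueError(f"{path}: row {row_no}: duplicate key {p.key}")
        seen.add(p.key)
        peaks.append(p)
    return peaks


def write_peak_list(path, peaks: list[PeakAssignment]):
    df = pd.DataFrame(
        [(p.residue_id, p.atom_label, p.h_shift, p.c_shift) for p in peaks],
        columns=PEAK_COLUMNS,
    )
    _write_df(path, df)


def write_csp_table(path, records: list[CSPRecord]):
    df = pd.DataFrame(
        [
            (r.residue_id, r.atom_label, r.delta_h, r.delta_c, r.weight, r.csp, r.significant)
            for r in records
        ],
        columns=["residue_id", "atom_label", "delta_h", "delta_c", "weight", "csp", "significant"],
    )
    _write_df(path, df)


# ----------------------------------------------------------------- titrations

def write_titration(path, series: TitrationSeries, sidecar: bool = True):
    data = {"point": np.arange(series.n_points), "lt_uM": series.lt_uM, "pt_uM": series.pt_uM}
    for key, vals in series.shifts.items():
        data[key] = vals
    _write_df(path, pd.DataFrame(data))
    if sidecar and series.meta:
        write_json(Path(path).with_suffix(".truth.json"), series.meta)


def read_titration(path) -> TitrationSeries:
    df = pd.read_csv(path)
    for col in ("lt_uM", "pt_uM"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    resid_cols = [c for c in df.columns if c not in ("point", "lt_uM", "pt_uM")]
    meta = {}
    sidecar = Path(path).with_suffix(".truth.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return TitrationSeries(
        lt_uM=df["lt_uM"].to_numpy(),
        pt_uM=df["pt_uM"].to_numpy(),
        shifts={c: df[c].to_numpy() for c in resid_cols},
        meta=meta,
    )


# ------------------------------------------------------- decays and buildups

def write_decay(path, series: DecaySeries, sidecar: bool = True):
    col = "g_gauss_per_cm" if series.x_role == "gradient" else "delay_s"
    _write_df(path, pd.DataFrame({col: series.x, "intensity": series.intensity}))
    header = {
        "x_role": series.x_role,
        "i0": series.i0,
        "diffusion_time_s": series.diffusion_time_s,
        "a_constant": series.a_constant,
    }
    if sidecar:
        header["meta"] = series.meta
    write_json(Path(path).with_suffix(".header.json"), header)


def read_decay(path) -> DecaySeries:
    df = pd.read_csv(path)
    header_path = Path(path).with_suffix(".header.json")
    header = json.loads(header_path.read_text()) if header_path.exists() else {}
    xcol = "g_gauss_per_cm" if "g_gauss_per_cm" in df.columns else "delay_s"
    return DecaySeries(
        x=df[xcol].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        x_role=header.get("x_role", "gradient"),
        i0=header.get("i0"),
        diffusion_time_s=header.get("diffusion_time_s"),
        a_constant=header.get("a_constant"),
        meta=header.get("meta", {}),
    )


def write_buildup(path, series: BuildupSeries, sidecar: bool = True):
    _write_df(
        path,
        pd.DataFrame(
            {"delay_ms": series.delays_s * 1e3, "ia": series.ia, "ib": series.ib}
        ),
    )
    if sidecar and series.meta:
        write_json(Path(path).with_suffix(".truth.json"), {"residue": series.residue, **series.meta})


def read_buildup(path) -> BuildupSeries:
    df = pd.read_csv(path)
    sidecar = Path(path).with_suffix(".truth.json")
    meta, residue = {}, ""
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        residue = meta.pop("residue", "")
    return BuildupSeries(
        delays_s=df["delay_ms"].to_numpy() * 1e-3,
        ia=df["ia"].to_numpy(),
        ib=df["ib"].to_numpy(),
        residue=residue,
        meta=meta,
    )


# ----------------------------------------------------------------- traces

def write_trace(path, freq_hz, intensity, lt_uM: float, pt_uM: float):
    _write_df(path, pd.DataFrame({"hz": freq_hz, "intensity": intensity}))
    write_json(Path(path).with_suffix(".header.json"), {"lt_uM": lt_uM, "pt_uM": pt_uM})


def read_trace(path):
    df = pd.read_csv(path)
    header = json.loads(Path(path).with_suffix(".header.json").read_text())
    return (
        df["hz"].to_numpy(),
        df["intensity"].to_numpy(),
        float(header["lt_uM"]),
        float(header["pt_uM"]),
    )


# -------------------------------------------------------------------- PDB

def write_multimodel_pdb(path, models: list[np.ndarray], element: str = "C"):
    """Write bead coordinate sets (nm) as a multi-model PDB (Å).

    Bead systems carry no chemistry; each bead becomes one pseudo-atom in
    its own residue so standard viewers and libraries can read the file.
    """
    lines = []
    for m, pos in enumerate(models, start=1):
        lines.append(f"MODEL     {m:4d}")
        for i, (x, y, z) in enumerate(np.asarray(pos) * 10.0, start=1):
            lines.append(
                f"ATOM  {i:5d}  {element:<3s}BEA A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_restraints_yaml(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)
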