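"""Tabular and JSON I/O for isotherms, dialysis wells, melt curves and spectra."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dialysis import DialysisWell
from .itc import Isotherm, TitrationProtocol
from .thermal import MeltCurve, SpectrumScan

__all__ = [
    "write_isotherm_tsv", "read_isotherm_tsv", "write_wells_tsv",
    "read_wells_tsv", "write_melt_tsv", "read_melt_tsv", "read_spectrum_tsv",
    "write_spectrum_tsv", "write_result_json", "sha256_of",
]


def write_isotherm_tsv(path: str | Path, isotherm: Isotherm,
                       protocol: Optional[TitrationProtocol] = None) -> None:
    n = len(isotherm)
    dv = (np.asarray(protocol.injection_volumes) * 1e6 if protocol is not None
          else np.full(n, np.nan))
    pd.DataFrame({
        "injection": np.arange(1, n + 1),
        "dV_uL": dv,
        "heat_kcal_per_mol": isotherm.heat,
        "molar_ratio": isotherm.molar_ratio,
    }).to_csv(path, sep="\t", index=False)


def read_isotherm_tsv(path: str | Path) -> tuple[Isotherm, np.ndarray]:
    """Returns the isotherm and the injection volumes (uL; NaN if absent)."""
    df = pd.read_csv(path, sep="\t")
    iso = Isotherm(molar_ratio=df["molar_ratio"].to_numpy(),
                   heat=df["heat_kcal_per_mol"].to_numpy())
    return iso, df["dV_uL"].to_numpy()


def write_wells_tsv(path: str | Path, wells: Sequence[DialysisWell]) -> None:
    pd.DataFrame({
        "protein_side_total_uM": [w.total_metal_protein_side * 1e6 for w in wells],
        "buffer_side_total_uM": [w.total_metal_buffer_side * 1e6 for w in wells],
        "protein_uM": [w.protein_conc * 1e6 for w in wells],
    }).to_csv(path, sep="\t", index=False)


def read_wells_tsv(path: str | Path) -> list[DialysisWell]:
    df = pd.read_csv(path, sep="\t")
    return [DialysisWell(total_metal_protein_side=row.protein_side_total_uM * 1e-6,
                         total_metal_buffer_side=row.buffer_side_total_uM * 1e-6,
                         protein_conc=row.protein_uM * 1e-6)
            for row in df.itertuples()]


def write_melt_tsv(path: str | Path, curve: MeltCurve) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# kind: {curve.kind}\n")
        pd.DataFrame({"temperature_C": curve.temperatures,
                      "value": curve.observable}).to_csv(fh, sep="\t", index=False)


def read_melt_tsv(path: str | Path, kind: Optional[str] = None) -> MeltCurve:
    path = Path(path)
    header_kind = None
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#") and "kind:" in first:
            header_kind = first.split("kind:")[1].strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    return MeltCurve(temperatures=df["temperature_C"].to_numpy(),
                     observable=df["value"].to_numpy(),
                     kind=kind or header_kind or "lambda_max")


def write_spectrum_tsv(path: str | Path, scan: SpectrumScan) -> None:
    pd.DataFrame({"wavelength_nm": scan.wavelengths,
                  "intensity": scan.intensities}).to_csv(path, sep="\t", index=False)


def read_spectrum_tsv(path: str | Path) -> SpectrumScan:
    df = pd.read_csv(path, sep="\t", comment="#")
    return SpectrumScan(wavelengths=df["wavelength_nm"].to_numpy(),
                        intensities=df["intensity"].to_numpy())


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_result_json(path: str | Path, payload: dict,
                      provenance: Optional[dict] = None) -> None:
    """Write a result envelope: ``{"result": ..., "provenance": ...}``."""
    doc = {"result": _jsonable(payload)}
    if provenance is not None:
        doc["provenance"] = _jsonable(provenance)
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
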