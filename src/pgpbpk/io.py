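"""Tabular readers/writers for the pipeline's file formats.

All tabular files are comma-separated with a header and fixed column order;
floats are written at 6 significant digits so diffs are bit-stable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .engine import SimulationResult
from .invitro import EnzymeKinetics, PlateAssay, StandardCurve

__all__ = [
    "read_plate",
    "write_plate",
    "read_standard_curve_data",
    "write_fit_report",
    "write_profile",
    "read_profile",
    "write_table",
]

_FLOAT_FMT = "%.6g"


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_plate(assay: PlateAssay, path: str | Path) -> None:
    """One row per well: substrate_mM, replicate, A340_t0, A340_t20."""
    rows = []
    for i, s in enumerate(assay.substrate_conc):
        for r in range(assay.replicates):
            rows.append(
                {
                    "substrate_mM": s,
                    "replicate": r + 1,
                    "A340_t0": assay.absorbance_t0[i][r],
                    "A340_t20": assay.absorbance_t20[i][r],
                }
            )
    write_table(pd.DataFrame(rows), path)


def read_plate(path: str | Path) -> PlateAssay:
    df = pd.read_csv(path)
    required = {"substrate_mM", "replicate", "A340_t0", "A340_t20"}
    if not required.issubset(df.columns):
        raise ValueError(f"plate file must have columns {sorted(required)}")
    sub = np.sort(df["substrate_mM"].unique())
    n_rep = int(df["replicate"].max())
    a0, a20 = [], []
    for s in sub:
        rows = df[df["substrate_mM"] == s].sort_values("replicate")
        if len(rows) != n_rep:
            raise ValueError(f"substrate level {s} mM has ragged replicates")
        a0.append(tuple(rows["A340_t0"]))
        a20.append(tuple(rows["A340_t20"]))
    return PlateAssay(
        substrate_conc=tuple(sub.tolist()),
        absorbance_t0=tuple(a0),
        absorbance_t20=tuple(a20),
        replicates=n_rep,
    )


def read_standard_curve_data(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Columns: nadh_nmol, absorbance."""
    df = pd.read_csv(path)
    if not {"nadh_nmol", "absorbance"}.issubset(df.columns):
        raise ValueError("standard-curve file must have columns nadh_nmol, absorbance")
    return df["nadh_nmol"].to_numpy(), df["absorbance"].to_numpy()


def write_fit_report(
    kinetics: EnzymeKinetics, curve: StandardCurve, path: str | Path
) -> None:
    lines = [
        "# Michaelis-Menten fit report",
        f"vmax_nmol_min_mg: {kinetics.vmax:.6g}",
        f"vmax_ci95: [{kinetics.vmax_ci[0]:.6g}, {kinetics.vmax_ci[1]:.6g}]",
        f"km_mM: {kinetics.km:.6g}",
        f"km_ci95: [{kinetics.km_ci[0]:.6g}, {kinetics.km_ci[1]:.6g}]",
        f"fit_r_squared: {kinetics.r_squared:.6g}" if kinetics.r_squared is not None else "fit_r_squared: NA",
        f"km_reliable: {kinetics.km_reliable}",
        f"standard_curve_slope: {curve.slope:.6g}",
        f"standard_curve_intercept: {curve.intercept:.6g}",
        f"standard_curve_r_squared: {curve.r_squared:.6g}",
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n")


def write_profile(
    result: SimulationResult, path: str | Path, per_compartment: bool = False
) -> None:
    data = {"time_h": result.times, "plasma_mg_per_L": result.plasma_conc}
    if per_compartment:
        for i, label in enumerate(result.labels):
            data[f"amount_{label}_mg"] = result.amounts[:, i]
    write_table(pd.DataFrame(data), path)


def read_profile(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"time_h", "plasma_mg_per_L"}.issubset(df.columns):
        raise ValueError("profile file must have columns time_h, plasma_mg_per_L")
    return df
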