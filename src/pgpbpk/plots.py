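"""Optional matplotlib figures for reports."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .engine import SimulationResult
from .saturation import PLAT_MG_L, SaturationScan

__all__ = ["plot_profile", "plot_dose_scan"]


def plot_profile(
    result: SimulationResult, path: str | Path, plat: float = PLAT_MG_L
) -> None:
    """Plasma concentration vs time with the toxicity threshold line."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(result.times, result.plasma_conc, lw=1.2)
    ax.axhline(plat, color="grey", ls=":", label=f"PLAT {plat:g} mg/L")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("plasma PG (mg/L)")
    ax.legend(frameon=False)
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_dose_scan(scan: SaturationScan, path: str | Path) -> None:
    """Dose vs observed clearance with the linear phase and onset marker."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(scan.dose_grid, scan.cl_observed, "o-", lw=1.2)
    if scan.linear_phase_fit is not None:
        f = scan.linear_phase_fit
        d = scan.dose_grid[: f.n_points]
        ax.plot(d, [f.predict(x) for x in d], "--", color="tab:orange",
                label=f"linear phase (r²={f.r_squared:.3f})")
    if scan.onset_dose is not None:
        ax.axvline(scan.onset_dose, color="tab:red", ls=":",
                   label=f"onset {scan.onset_dose:g} mg/kg")
    ax.set_xscale("log")
    ax.set_xlabel("dose (mg/kg per event)")
    ax.set_ylabel("observed CL (L/h)")
    ax.set_title(f"{scan.group}, q{scan.interval:g}h")
    ax.legend(frameon=False)
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
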