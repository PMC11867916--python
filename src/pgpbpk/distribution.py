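"""Tissue:plasma partition coefficients and steady-state distribution volume.

Kp values are predicted from tissue composition by the classic
oil/water-surrogate method for non-adipose tissues, with the corrected
tissue-binding convention: a neutral solute distributes between neutral
lipid (oil-like, partition P = 10^logP), phospholipid (treated as 30% lipid
/ 70% water) and tissue water, and the plasma:tissue protein-binding
asymmetry enters as fu_p/fu_t with fu_t estimated from fu_p assuming tissue
interstitial binding at half the plasma strength (adipose is treated as
binding-free, fu_t = 1).

A uniform Kp scalar multiplies every predicted tissue Kp; the neonatal
model uses 0.44 to recover the observed (smaller) distribution volume.
"""

from __future__ import annotations

import importlib.resources
from typing import Mapping

import pandas as pd
import yaml
from pydantic import BaseModel, model_validator

from .population import TISSUES, Subject
from .units import CompoundParams

__all__ = [
    "TissueComposition",
    "KpSet",
    "load_tissue_compositions",
    "predict_kp",
    "predict_kp_set",
    "compute_vss",
]


class TissueComposition(BaseModel):
    """Volume fractions of water, neutral lipid and phospholipid."""

    tissue: str
    f_water: float
    f_neutral_lipid: float
    f_phospholipid: float

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "TissueComposition":
        for f in (self.f_water, self.f_neutral_lipid, self.f_phospholipid):
            if not 0 <= f <= 1:
                raise ValueError("composition fractions must lie in [0, 1]")
        if self.f_water + self.f_neutral_lipid + self.f_phospholipid > 1 + 1e-9:
            raise ValueError("composition fractions must sum to <= 1")
        return self


class KpSet(BaseModel):
    """Tissue -> Kp map plus the uniform scalar applied on top."""

    kp: Mapping[str, float]
    kp_scalar: float = 1.0

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "KpSet":
        if any(v <= 0 for v in self.kp.values()):
            raise ValueError("all Kp must be positive")
        if self.kp_scalar <= 0:
            raise ValueError("kp_scalar must be positive")
        return self

    def scaled(self, tissue: str) -> float:
        return self.kp[tissue] * self.kp_scalar

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tissue": list(self.kp),
                "kp": list(self.kp.values()),
                "kp_scaled": [self.scaled(t) for t in self.kp],
            }
        )


def load_tissue_compositions() -> dict[str, TissueComposition]:
    """Shipped human composition table, keyed by tissue (plus 'plasma')."""
    ref = importlib.resources.files("pgpbpk.data") / "tissue_composition.yaml"
    raw = yaml.safe_load(ref.read_text())
    return {name: TissueComposition(tissue=name, **vals) for name, vals in raw.items()}


def _solubility_capacity(p_vow: float, comp: TissueComposition) -> float:
    """P*(f_nl + 0.3 f_ph) + (f_w + 0.7 f_ph)."""
    return p_vow * (comp.f_neutral_lipid + 0.3 * comp.f_phospholipid) + (
        comp.f_water + 0.7 * comp.f_phospholipid
    )


def _fu_tissue(fu_plasma: float, adipose: bool) -> float:
    """Tissue unbound fraction from the plasma one.

    Non-adipose interstitial/cellular protein binding is assumed half as
    strong as plasma binding: fu_t = 1 / (1 + 0.5*(1-fu_p)/fu_p).
    """
    if adipose:
        return 1.0
    return 1.0 / (1.0 + 0.5 * (1.0 - fu_plasma) / fu_plasma)


def predict_kp(
    compound: CompoundParams,
    tissue: TissueComposition,
    plasma: TissueComposition,
) -> float:
    """Predicted tissue:plasma partition coefficient for a neutral solute."""
    p_vow = 10.0**compound.log_p
    num = _solubility_capacity(p_vow, tissue)
    den = _solubility_capacity(p_vow, plasma)
    if den <= 0:
        raise ValueError("plasma solubility capacity must be positive")
    fu_t = _fu_tissue(compound.fu_plasma, adipose=tissue.tissue == "adipose")
    return num / den * compound.fu_plasma / fu_t


def predict_kp_set(
    compound: CompoundParams,
    kp_scalar: float = 1.0,
    compositions: Mapping[str, TissueComposition] | None = None,
) -> KpSet:
    """Predict Kp for every model tissue from the shipped composition table."""
    comps = dict(compositions) if compositions is not None else load_tissue_compositions()
    plasma = comps["plasma"]
    kp = {t: predict_kp(compound, comps[t], plasma) for t in TISSUES}
    return KpSet(kp=kp, kp_scalar=kp_scalar)


def compute_vss(subject: Subject, kps: KpSet, compound: CompoundParams) -> float:
    """Steady-state volume of distribution in L/kg, referenced to plasma.

    Vss = (plasma-equivalent blood volume + sum_t V_t * Kp_t * scalar) / BW.
    The blood pool enters as V_blood * B:P, the plasma-equivalent volume of
    whole blood.
    """
    missing = [t for t in TISSUES if t not in kps.kp]
    if missing:
        raise KeyError(f"Kp missing for tissues: {missing}")
    v_blood = subject.organ_volumes["venous"] + subject.organ_volumes["arterial"]
    v = v_blood * compound.blood_to_plasma
    for t in TISSUES:
        v += subject.organ_volumes[t] * kps.scaled(t)
    return v / subject.weight
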