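"""Tissue-to-plasma partitioning for neutral compounds (Rodgers-single).

Carbamazepine (amide, pKa 10.86) and its epoxide are effectively un-ionized at
physiologic pH, so only the neutral-species terms of the Rodgers-Rowland
composition equations are used: partitioning into tissue water, neutral lipid,
neutral phospholipid, and residual binding to tissue interstitial protein
scaled by the tissue:plasma albumin ratio.  Adipose uses the vegetable-oil
partition surrogate instead of the octanol logP, the usual correction for
bulk-lipid tissue.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict

from .parameters import (
    CompoundParameters,
    ConfigurationError,
    Physiology,
    TISSUES,
    TissueData,
)


class KpSet(BaseModel):
    model_config = ConfigDict(frozen=True)

    values: dict[str, float]

    def __getitem__(self, tissue: str) -> float:
        return self.values[tissue]


def _lipid_partition(logP: float, adipose: bool) -> float:
    # vegetable oil:water surrogate for adipose (Poulin & Theil correlation)
    if adipose:
        return 10.0 ** (1.115 * logP - 1.35)
    return 10.0 ** logP


def compute_kp(compound: CompoundParameters, tissue: TissueData,
               plasma_composition: dict[str, float], *, adipose: bool = False) -> float:
    """Tissue:plasma partition coefficient for a neutral compound.

    Kp = fu_p * [ f_EW + f_IW + P*f_NL + (0.3P+0.7)*f_NP
                  + (1/fu_p - 1 - P*f_NL,p - (0.3P+0.7)*f_NP,p) * PRt/PRp ]
    """
    for name in ("f_water", "f_nl", "f_np"):
        if name not in plasma_composition:
            raise ConfigurationError(f"plasma composition missing {name!r}")
    p_tissue = _lipid_partition(compound.logP, adipose)
    p_plasma = _lipid_partition(compound.logP, adipose=False)
    plasma_lipid = (p_plasma * plasma_composition["f_nl"]
                    + (0.3 * p_plasma + 0.7) * plasma_composition["f_np"])
    protein_term = max(1.0 / compound.fu_p - 1.0 - plasma_lipid, 0.0)
    kpu = (tissue.f_ew + tissue.f_iw
           + p_tissue * tissue.f_nl
           + (0.3 * p_tissue + 0.7) * tissue.f_np
           + protein_term * tissue.pr_ratio)
    kp = kpu * compound.fu_p
    if kp <= 0:
        raise ConfigurationError("non-positive Kp from composition table")
    return kp


def compute_kp_set(compound: CompoundParameters, physiology: Physiology) -> KpSet:
    values = {
        name: compute_kp(compound, physiology.tissues[name],
                         physiology.plasma_composition, adipose=(name == "adipose"))
        for name in TISSUES
    }
    return KpSet(values=values)


def erythrocyte_partition(Rbp: float, hematocrit: float) -> float:
    """Erythrocyte:plasma ratio implied by the blood:plasma ratio."""
    return max((Rbp - (1.0 - hematocrit)) / hematocrit, 0.0)


def compute_vss(kps: KpSet, physiology: Physiology, fu_p: float, Rbp: float) -> float:
    """Steady-state distribution volume (L/kg, plasma reference).

    Vss = (V_plasma + V_ery * E:P + sum_t Kp_t * V_t) / body weight.
    fu_p enters through the Kp values themselves; it is accepted here so the
    signature states the full parameter dependence of the metric.
    """
    del fu_p  # already folded into the KpSet
    v_blood = physiology.blood["volume_total_L"]
    v_plasma = v_blood * (1.0 - physiology.hematocrit)
    v_ery = v_blood * physiology.hematocrit
    tissue_term = sum(kps[t] * physiology.tissues[t].volume_L for t in TISSUES)
    total = v_plasma + v_ery * erythrocyte_partition(Rbp, physiology.hematocrit) + tissue_term
    return total / physiology.body_weight_kg
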