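"""Interspecies and in-vitro-to-in-vivo scaling of the human model inputs.

This module derives the human drug parameters from preclinical and in vitro
measurements:

* absorption rate constant Ka from Caco-2 permeability via an empirical
  Peff correlation and the cylindrical-intestine relation Ka = 2·Peff/r;
* steady-state volume of distribution V_SS by allometry on rat, monkey and
  dog data;
* human tissue partition coefficients by scaling rat Kp,SS with a single
  scalar chosen so the Øie–Tozer V_SS matches the allometric prediction,
  with an extraction-ratio correction for eliminating organs;
* hepatic enzyme Vmax by IVIVE (ISEF × CYP abundance × MPPGL × liver mass).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_config import PhysiologySet, TISSUES


@dataclass
class AllometricFit:
    """Power-law V_SS(BW) = a·BW^b fitted in log–log space."""

    coefficient_l: float  # a, litres at 1 kg
    exponent: float  # b
    points: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class KpDerivation:
    """Record of the rat-to-human Kp scaling chain."""

    rat_kp_ss: dict[str, float]
    kp_scalar: float
    extraction_ratio: float
    final_kp: dict[str, float]


@dataclass
class IVIVEParams:
    """Inputs for scaling recombinant-CYP kinetics to the whole liver."""

    hlm_activity_pmol_min_mg: float
    rcyp_activity_pmol_min_pmol: float
    cyp_abundance_nmol_mg: float
    mppgl_mg_g: float
    liver_mass_g: float

    def __post_init__(self) -> None:
        for name in (
            "hlm_activity_pmol_min_mg",
            "rcyp_activity_pmol_min_pmol",
            "cyp_abundance_nmol_mg",
            "mppgl_mg_g",
            "liver_mass_g",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def peff_from_papp(papp_nm_s: float) -> float:
    """Effective human intestinal permeability (µm/s) from Caco-2 Papp (nm/s).

    Empirical log-linear correlation:
    log10(Peff) = 0.4926·log10(Papp) − 0.1454.
    """
    if papp_nm_s <= 0:
        raise ValueError("papp must be > 0")
    return 10.0 ** (0.4926 * np.log10(papp_nm_s) - 0.1454)


def ka_from_peff(peff_um_s: float, radius_cm: float = 1.75) -> float:
    """First-order absorption rate constant (1/min) from Peff.

    Treats the intestine as a cylinder of the given radius:
    Ka = 2·Peff / radius, with Peff converted from µm/s to cm/min.
    """
    if peff_um_s <= 0 or radius_cm <= 0:
        raise ValueError("peff and radius must be > 0")
    peff_cm_min = peff_um_s * 1e-4 * 60.0
    return 2.0 * peff_cm_min / radius_cm


def fit_allometric(points: list[tuple[float, float]]) -> AllometricFit:
    """Fit V_SS = a·BW^b by ordinary least squares on (ln BW, ln V_SS).

    ``points`` are (body weight kg, total V_SS L) pairs; at least two
    distinct body weights are required.
    """
    if len(points) < 2:
        raise ValueError("allometric fit needs at least 2 points")
    bw = np.array([p[0] for p in points], dtype=float)
    vss = np.array([p[1] for p in points], dtype=float)
    if np.any(bw <= 0) or np.any(vss <= 0):
        raise ValueError("body weights and volumes must be > 0")
    if np.unique(bw).size < 2:
        raise ValueError("allometric fit needs at least 2 distinct body weights")
    b, ln_a = np.polyfit(np.log(bw), np.log(vss), 1)
    return AllometricFit(coefficient_l=float(np.exp(ln_a)), exponent=float(b),
                         points=list(points))


def predict_vss(fit: AllometricFit, body_weight_kg: float) -> float:
    """Total V_SS (L) predicted by the allometric power law."""
    if body_weight_kg <= 0:
        raise ValueError("body weight must be > 0")
    return fit.coefficient_l * body_weight_kg ** fit.exponent


def erythrocyte_partition(r: float, hct: float) -> float:
    """Erythrocyte-to-plasma partition coefficient EP = 1 + (R − 1)/Hct."""
    if not 0 < hct < 1:
        raise ValueError("hematocrit must be in (0, 1)")
    if r <= 0:
        raise ValueError("blood/plasma ratio must be > 0")
    return 1.0 + (r - 1.0) / hct


def _blood_terms(physiology: PhysiologySet, r: float) -> tuple[float, float]:
    """(Vp, Vrbc·EP) in mL, splitting total blood volume by hematocrit."""
    hct = physiology.hematocrit
    v_blood = physiology.blood_volume_ml
    vp = (1.0 - hct) * v_blood
    vrbc = hct * v_blood
    return vp, vrbc * erythrocyte_partition(r, hct)


def oie_tozer_vss(
    physiology: PhysiologySet, kp_map: dict[str, float], r: float
) -> float:
    """Øie–Tozer steady-state volume of distribution, in litres.

    V_SS = Vp + Vrbc·EP + Σ V_T·Kp_T, with plasma and red-cell volumes split
    from total blood volume by the hematocrit.
    """
    missing = [t for t in TISSUES if t not in kp_map]
    if missing:
        raise ValueError(f"kp_map missing tissue(s): {missing}")
    vp, vrbc_ep = _blood_terms(physiology, r)
    tissue_term = sum(
        physiology.tissue(t).volume_ml * kp_map[t] for t in TISSUES
    )
    return (vp + vrbc_ep + tissue_term) / 1000.0


def solve_kp_scalar(
    physiology: PhysiologySet,
    rat_kp: dict[str, float],
    r: float,
    target_vss_l: float,
) -> float:
    """Scalar s such that Øie–Tozer V_SS with s·Kp,SS equals the target.

    Closed form: s = (V_target − Vp − Vrbc·EP) / Σ V_T·Kp,SS.
    """
    vp, vrbc_ep = _blood_terms(physiology, r)
    blood_l = (vp + vrbc_ep) / 1000.0
    if target_vss_l < blood_l:
        raise ValueError(
            f"target V_SS {target_vss_l:.3g} L is below the blood "
            f"contribution {blood_l:.3g} L"
        )
    tissue_term_l = sum(
        physiology.tissue(t).volume_ml * rat_kp[t] for t in TISSUES
    ) / 1000.0
    return (target_vss_l - blood_l) / tissue_term_l


def scale_kp(rat_kp: dict[str, float], scalar: float) -> dict[str, float]:
    """Element-wise Kp scaling (full precision; round only for display)."""
    if scalar <= 0:
        raise ValueError("kp scalar must be > 0")
    return {t: kp * scalar for t, kp in rat_kp.items()}


def correct_eliminating_kp(kp_scaled: float, er: float) -> float:
    """Correct an eliminating organ's apparent Kp for extraction.

    The AUC-ratio Kp of an eliminating organ understates the equilibrium
    partition coefficient by the organ availability (1 − ER):
    Kp = Kp_apparent / (1 − ER).
    """
    if not 0 <= er < 1:
        raise ValueError("extraction ratio must be in [0, 1)")
    return kp_scaled / (1.0 - er)


def isef(
    hlm_activity_pmol_min_mg: float,
    rcyp_activity_pmol_min_pmol: float,
    cyp_abundance_nmol_mg: float,
) -> float:
    """Inter-system extrapolation factor (recombinant CYP → microsomes).

    ISEF = HLM activity / (rCYP activity × abundance), with the CYP
    abundance converted from nmol/mg to pmol/mg.  Full precision is
    returned; round only for display.
    """
    if min(hlm_activity_pmol_min_mg, rcyp_activity_pmol_min_pmol,
           cyp_abundance_nmol_mg) <= 0:
        raise ValueError("all ISEF inputs must be > 0")
    abundance_pmol_mg = cyp_abundance_nmol_mg * 1000.0
    return hlm_activity_pmol_min_mg / (
        rcyp_activity_pmol_min_pmol * abundance_pmol_mg
    )


def liver_vmax(
    vmax_pmol_min_pmol_cyp: float,
    isef_value: float,
    cyp_abundance_nmol_mg: float,
    mppgl_mg_g: float,
    liver_mass_g: float,
) -> float:
    """Whole-liver Vmax (nmol/min) from a per-pmol-CYP recombinant rate.

    Vmax = rate × ISEF × abundance (pmol/mg) × MPPGL (mg/g) × liver mass (g),
    converted from pmol/min to nmol/min.
    """
    if vmax_pmol_min_pmol_cyp < 0:
        raise ValueError("per-pmol Vmax must be >= 0")
    if isef_value < 0:
        raise ValueError("ISEF must be >= 0")
    if min(cyp_abundance_nmol_mg, mppgl_mg_g, liver_mass_g) <= 0:
        raise ValueError("abundance, MPPGL and liver mass must be > 0")
    abundance_pmol_mg = cyp_abundance_nmol_mg * 1000.0
    pmol_min = (
        vmax_pmol_min_pmol_cyp
        * isef_value
        * abundance_pmol_mg
        * mppgl_mg_g
        * liver_mass_g
    )
    return pmol_min / 1000.0


def derive_human_kp(
    physiology: PhysiologySet,
    rat_kp: dict[str, float],
    r: float,
    kp_scalar: float,
    er: float,
    eliminating: tuple[str, ...] = ("Liver",),
) -> KpDerivation:
    """Full rat-to-human Kp chain: scale, then ER-correct eliminating organs.

    By default only the liver is treated as eliminating.
    """
    scaled = scale_kp(rat_kp, kp_scalar)
    final = dict(scaled)
    for t in eliminating:
        final[t] = correct_eliminating_kp(scaled[t], er)
    return KpDerivation(
        rat_kp_ss=dict(rat_kp), kp_scalar=kp_scalar, extraction_ratio=er,
        final_kp=final,
    )
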