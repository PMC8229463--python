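"""Hepatic intrinsic clearance, extraction, and oral bioavailability.

The unbound hepatic intrinsic clearance is assembled from the enzyme
pathways and a residual term:

    CLu,int = Σ Vmax / (Km · fu,mic) + CLu,add

Each pathway's Vmax/Km (nmol/min over µM) is a clearance in mL/min; dividing
by the unbound microsomal fraction converts it to an unbound-drug basis.
CLu,add collects biliary excretion and any hepatic elimination not covered
by the measured pathways.  Pathway fractions fm are the components' shares
of the total.

Hepatic availability follows the well-stirred liver model on a blood-flow
basis: Fh = Q_LI·R / (Q_LI·R + fup·CLu,int), ER = 1 − Fh, and oral
bioavailability F = Fa·Fg·Fh.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .model_config import DrugParameters

#: Key under which the residual (non-enzymatic) clearance appears in the
#: pathway-fraction map.
ADDITIONAL = "CLu,add"


@dataclass
class ClearanceModel:
    """Decomposed unbound hepatic intrinsic clearance (mL/min)."""

    pathway_clints: dict[str, float]
    clu_add: float
    clu_int_total: float
    fm: dict[str, float]
    fu_li: float  # unbound liver fraction fup/Kp_liver, reported only


@dataclass
class BioavailabilityResult:
    fa: float
    fg: float
    fh: float
    er: float
    f_total: float


def build_clu_int(drug: DrugParameters) -> ClearanceModel:
    """Assemble CLu,int and the metabolic-pathway fractions from drug inputs."""
    if drug.fu_mic <= 0:
        raise ValueError("fu_mic must be > 0")
    pathway_clints = {
        p.label: p.vmax_nmol_min / (p.km_um * drug.fu_mic)
        for p in drug.enzyme_pathways
    }
    total = sum(pathway_clints.values()) + drug.clu_add_ml_min
    if total < 0:
        raise ValueError("total intrinsic clearance must be >= 0")
    if total > 0:
        fm = {label: cl / total for label, cl in pathway_clints.items()}
        fm[ADDITIONAL] = drug.clu_add_ml_min / total
    else:
        # a non-eliminating drug is a valid closed-system limit; the
        # pathway fractions are undefined and reported as zero
        fm = {label: 0.0 for label in pathway_clints}
        fm[ADDITIONAL] = 0.0
    fu_li = drug.fup / drug.kp_map["Liver"]
    return ClearanceModel(
        pathway_clints=pathway_clints,
        clu_add=drug.clu_add_ml_min,
        clu_int_total=total,
        fm=fm,
        fu_li=fu_li,
    )


def hepatic_availability(
    clu_int_ml_min: float, fup: float, q_liver_ml_min: float, r: float
) -> BioavailabilityResult:
    """Well-stirred hepatic availability and extraction ratio.

    Returns a partial :class:`BioavailabilityResult` carrying fh and er
    (fa, fg and f_total are set to NaN placeholders).
    """
    if min(fup, q_liver_ml_min, r) <= 0 or clu_int_ml_min < 0:
        raise ValueError("fup, liver flow and R must be > 0; CLu,int >= 0")
    q_blood = q_liver_ml_min * r
    fh = q_blood / (q_blood + fup * clu_int_ml_min)
    return BioavailabilityResult(
        fa=float("nan"), fg=float("nan"), fh=fh, er=1.0 - fh, f_total=float("nan")
    )


def oral_bioavailability(fa: float, fg: float, fh: float) -> float:
    """Absolute oral bioavailability F = Fa·Fg·Fh."""
    if min(fa, fg, fh) <= 0:
        raise ValueError("fa, fg and fh must be > 0")
    if fa > 1:
        warnings.warn(
            f"fa = {fa:.3g} exceeds 1 (apparent fitted value)", stacklevel=2
        )
    return fa * fg * fh


def bioavailability(drug: DrugParameters, q_liver_ml_min: float) -> BioavailabilityResult:
    """Full closed-form bioavailability from drug parameters and liver flow."""
    model = build_clu_int(drug)
    partial = hepatic_availability(
        model.clu_int_total, drug.fup, q_liver_ml_min, drug.blood_plasma_ratio
    )
    f = oral_bioavailability(drug.fa, drug.fg, partial.fh)
    return BioavailabilityResult(
        fa=drug.fa, fg=drug.fg, fh=partial.fh, er=partial.er, f_total=f
    )
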