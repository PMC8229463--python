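"""Domain types, built-in parameter tables, and file I/O.

The package works in a single internal unit system: volumes in mL, flows and
clearances in mL/min, time in min, amounts in ng, concentrations in ng/mL.
Michaelis constants are kept in µM, which equals nmol/mL, so Vmax (nmol/min)
divided by Km (µM) is a clearance in mL/min without invoking the molecular
weight.  Doses are entered in mg at user boundaries and converted to ng
(1 mg = 1e6 ng) internally.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

MG_TO_NG = 1.0e6

#: Canonical tissue labels of the 11 perfused tissue compartments, in the
#: order used throughout the package.
TISSUES: tuple[str, ...] = (
    "Adipose",
    "Adrenal gland",
    "Brain",
    "Heart",
    "Kidney",
    "Large intestine",
    "Liver",
    "Lung",
    "Small intestine",
    "Spleen",
    "Stomach",
)

Drainage = Literal["systemic-venous", "portal-to-liver", "lung-series"]

#: Venous drainage of each tissue: splanchnic organs drain into the portal
#: vein and reach the liver first; the lung sits in series between the venous
#: and arterial pools; everything else drains directly into venous blood.
DEFAULT_DRAINAGE: dict[str, Drainage] = {
    "Adipose": "systemic-venous",
    "Adrenal gland": "systemic-venous",
    "Brain": "systemic-venous",
    "Heart": "systemic-venous",
    "Kidney": "systemic-venous",
    "Large intestine": "portal-to-liver",
    "Liver": "systemic-venous",
    "Lung": "lung-series",
    "Small intestine": "portal-to-liver",
    "Spleen": "portal-to-liver",
    "Stomach": "portal-to-liver",
}

PORTAL_TISSUES: tuple[str, ...] = tuple(
    t for t in TISSUES if DEFAULT_DRAINAGE[t] == "portal-to-liver"
)
#: Tissues whose venous outflow enters the systemic venous pool directly
#: (the liver's outflow is systemic as well, but it is handled explicitly).
SYSTEMIC_TISSUES: tuple[str, ...] = tuple(
    t
    for t in TISSUES
    if DEFAULT_DRAINAGE[t] == "systemic-venous" and t != "Liver"
)


class TissueSpec(BaseModel):
    """One perfused tissue: anatomical volume, blood flow, drainage, Kp."""

    model_config = ConfigDict(validate_assignment=True)

    name: str
    volume_ml: float = Field(gt=0)
    blood_flow_ml_min: float = Field(ge=0)
    drainage: Drainage
    kp: Optional[float] = None

    @field_validator("kp")
    @classmethod
    def _kp_positive(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v <= 0:
            raise ValueError("kp must be > 0 when set")
        return v


class PhysiologySet(BaseModel):
    """Reference physiology: tissue volumes/flows, blood pools, cardiac output.

    The residual flow ``residual_flow_ml_min`` (Q_RE) is the part of cardiac
    output perfusing tissues not represented explicitly; it acts as a pure
    arterial-to-venous shunt in the circulation model.
    """

    model_config = ConfigDict(validate_assignment=True)

    tissues: list[TissueSpec]
    venous_blood_volume_ml: float = Field(gt=0)
    arterial_blood_volume_ml: float = Field(gt=0)
    cardiac_output_ml_min: float = Field(gt=0)
    hematocrit: float = Field(gt=0, lt=1)
    body_weight_kg: float = Field(gt=0)

    @model_validator(mode="after")
    def _check_flows(self) -> "PhysiologySet":
        names = [t.name for t in self.tissues]
        missing = [t for t in TISSUES if t not in names]
        if missing:
            raise ValueError(f"missing tissue(s): {', '.join(missing)}")
        if self.residual_flow_ml_min < 0:
            raise ValueError(
                "residual_flow_ml_min (cardiac output minus systemic organ "
                f"flows) is negative: {self.residual_flow_ml_min:.1f}"
            )
        portal = sum(self.tissue(t).blood_flow_ml_min for t in PORTAL_TISSUES)
        q_li = self.tissue("Liver").blood_flow_ml_min
        if portal > q_li + 1e-9:
            raise ValueError(
                f"portal inflow {portal:.1f} mL/min exceeds liver blood flow "
                f"{q_li:.1f} mL/min"
            )
        q_lu = self.tissue("Lung").blood_flow_ml_min
        if abs(q_lu - self.cardiac_output_ml_min) > 1e-6 * self.cardiac_output_ml_min:
            raise ValueError(
                f"lung blood flow {q_lu:.1f} must equal cardiac output "
                f"{self.cardiac_output_ml_min:.1f} (series circulation)"
            )
        return self

    def tissue(self, name: str) -> TissueSpec:
        for t in self.tissues:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def blood_volume_ml(self) -> float:
        return self.venous_blood_volume_ml + self.arterial_blood_volume_ml

    @property
    def residual_flow_ml_min(self) -> float:
        """Q_RE: cardiac output minus the explicit systemic organ flows.

        Portal tissues are excluded because their perfusion returns through
        the liver; the lung is excluded because it carries the whole cardiac
        output in series.
        """
        q_organs = sum(
            self.tissue(t).blood_flow_ml_min for t in SYSTEMIC_TISSUES
        ) + self.tissue("Liver").blood_flow_ml_min
        return self.cardiac_output_ml_min - q_organs

    @property
    def hepatic_arterial_flow_ml_min(self) -> float:
        """Hepatic arterial supply: liver outflow minus portal inflow."""
        portal = sum(self.tissue(t).blood_flow_ml_min for t in PORTAL_TISSUES)
        return self.tissue("Liver").blood_flow_ml_min - portal


class EnzymePathway(BaseModel):
    """Michaelis–Menten kinetics of one hepatic metabolic pathway."""

    label: str
    vmax_nmol_min: float = Field(ge=0)
    km_um: float = Field(gt=0)


class DrugParameters(BaseModel):
    """Drug-specific model inputs.

    ``fa`` above 1 is tolerated with a warning: per-subject fits of an
    apparent absorbed fraction can exceed unity even though the physical
    quantity cannot.
    """

    model_config = ConfigDict(validate_assignment=True)

    fup: float = Field(gt=0, le=1)
    blood_plasma_ratio: float = Field(gt=0)
    ka_per_min: float = Field(gt=0)
    fa: float = Field(gt=0)
    fg: float = Field(default=1.0, gt=0, le=1)
    fu_mic: float = Field(gt=0, le=1)
    clu_add_ml_min: float = Field(ge=0)
    enzyme_pathways: list[EnzymePathway]
    kp_map: dict[str, float]
    pka: Optional[float] = None
    logp: Optional[float] = None

    @field_validator("fa")
    @classmethod
    def _warn_large_fa(cls, v: float) -> float:
        if v > 1:
            warnings.warn(
                f"fa = {v:.3g} exceeds 1; treating it as an apparent "
                "(fitted) absorbed fraction",
                stacklevel=2,
            )
        return v

    @model_validator(mode="after")
    def _check_kp_map(self) -> "DrugParameters":
        unknown = set(self.kp_map) - set(TISSUES)
        if unknown:
            raise ValueError(f"unknown tissue label(s) in kp_map: {sorted(unknown)}")
        missing = set(TISSUES) - set(self.kp_map)
        if missing:
            raise ValueError(f"kp_map missing tissue(s): {sorted(missing)}")
        bad = {t: v for t, v in self.kp_map.items() if v <= 0}
        if bad:
            raise ValueError(f"non-positive Kp: {bad}")
        return self


Route = Literal["PO", "IV"]


class DoseEvent(BaseModel):
    time_min: float = Field(ge=0)
    route: Route
    amount_ng: float = Field(gt=0)


class DoseRegimen(BaseModel):
    """Ordered dosing events; times must be strictly increasing."""

    events: list[DoseEvent]

    @model_validator(mode="after")
    def _check_order(self) -> "DoseRegimen":
        if not self.events:
            raise ValueError("regimen must contain at least one dose event")
        times = [e.time_min for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose event times must be strictly increasing")
        return self

    @classmethod
    def once_daily(
        cls, dose_mg: float, n_doses: int = 1, tau_h: float = 24.0, route: Route = "PO"
    ) -> "DoseRegimen":
        return cls(
            events=[
                DoseEvent(
                    time_min=i * tau_h * 60.0, route=route, amount_ng=dose_mg * MG_TO_NG
                )
                for i in range(n_doses)
            ]
        )


class ConcTimeSeries(BaseModel):
    """One subject's plasma concentration–time record."""

    subject_id: str
    dose_mg: float = Field(gt=0)
    times_min: list[float]
    conc_ng_ml: list[float]
    day: int = 1

    @model_validator(mode="after")
    def _check_series(self) -> "ConcTimeSeries":
        if len(self.times_min) != len(self.conc_ng_ml):
            raise ValueError("times and concentrations differ in length")
        if any(
            t2 <= t1 for t1, t2 in zip(self.times_min, self.times_min[1:])
        ):
            raise ValueError("sampling times must be strictly increasing")
        if any(c < 0 for c in self.conc_ng_ml):
            raise ValueError("concentrations must be non-negative")
        return self


# ---------------------------------------------------------------------------
# Built-in parameter tables
# ---------------------------------------------------------------------------

# Reference human physiology (70 kg): tissue volume (mL) and blood flow
# (mL/min).  Cardiac output 5200 mL/min; the lung carries all of it.
_HUMAN_TISSUES: dict[str, tuple[float, float]] = {
    "Adipose": (15000.0, 270.0),
    "Adrenal gland": (14.0, 15.6),
    "Brain": (1400.0, 593.0),
    "Heart": (329.0, 208.0),
    "Kidney": (308.0, 910.0),
    "Large intestine": (371.0, 208.0),
    "Liver": (1800.0, 1326.0),
    "Lung": (532.0, 5200.0),
    "Small intestine": (520.0, 520.0),
    "Spleen": (182.0, 104.0),
    "Stomach": (147.0, 52.0),
}

#: Steady-state tissue-to-plasma partition coefficients of fexuprazan
#: measured in rat (AUC_tissue / AUC_plasma).
RAT_KP_SS: dict[str, float] = {
    "Adipose": 11.7,
    "Adrenal gland": 56.1,
    "Brain": 3.55,
    "Heart": 12.4,
    "Kidney": 44.2,
    "Large intestine": 110.0,
    "Liver": 417.0,
    "Lung": 236.0,
    "Small intestine": 637.0,
    "Spleen": 47.9,
    "Stomach": 519.0,
}

#: Human tissue Kp used by the model: rat Kp,SS scaled by the empirical
#: Kp scalar 0.371 (liver additionally corrected for hepatic extraction).
HUMAN_KP: dict[str, float] = {
    "Adipose": 4.32,
    "Adrenal gland": 20.8,
    "Brain": 1.32,
    "Heart": 4.60,
    "Kidney": 16.4,
    "Large intestine": 40.8,
    "Liver": 303.0,
    "Lung": 87.6,
    "Small intestine": 124.0,
    "Spleen": 17.8,
    "Stomach": 193.0,
}

#: Empirical scalar multiplying rat Kp,SS so the Øie–Tozer volume of
#: distribution matches the allometric human prediction.
KP_SCALAR: float = 0.371

#: Preclinical steady-state volumes of distribution used for the allometric
#: fit: (body weight kg, V_SS L/kg).
PRECLINICAL_VSS: dict[str, tuple[float, float]] = {
    "rat": (0.25, 20.2),
    "monkey": (4.0, 9.17),
    "dog": (10.0, 12.6),
}

#: Caco-2 apparent permeability (apical→basolateral), nm/s.
CACO2_PAPP_NM_S: float = 165.0
#: Effective radius of the human small intestine treated as a cylinder, cm.
INTESTINAL_RADIUS_CM: float = 1.75

#: In-vitro-to-in-vivo extrapolation constants for hepatic CYP3A4 kinetics.
IVIVE_DEFAULTS: dict[str, float] = {
    # testosterone 6β-hydroxylation in pooled human liver microsomes
    "hlm_activity_pmol_min_mg": 6100.0,
    # the same reaction in the recombinant CYP3A4 system
    "rcyp_activity_pmol_min_pmol": 200.0,
    # CYP3A4 abundance in human liver microsomes, nmol/mg protein
    "cyp_abundance_nmol_mg": 0.079,
    # microsomal protein per gram of liver
    "mppgl_mg_g": 39.79,
}


def default_physiology() -> PhysiologySet:
    """Reference 70 kg human physiology used throughout the package."""
    return PhysiologySet(
        tissues=[
            TissueSpec(
                name=name,
                volume_ml=vol,
                blood_flow_ml_min=flow,
                drainage=DEFAULT_DRAINAGE[name],
            )
            for name, (vol, flow) in _HUMAN_TISSUES.items()
        ],
        venous_blood_volume_ml=3470.0,
        arterial_blood_volume_ml=1730.0,
        cardiac_output_ml_min=5200.0,
        hematocrit=0.45,
        body_weight_kg=70.0,
    )


def default_drug_parameters() -> DrugParameters:
    """Fexuprazan model inputs for the reference human.

    Fa (0.761) and the additional intrinsic clearance CLu,add (12.9 L/min)
    are the pooled estimates from per-subject fits; Ka is predicted from
    Caco-2 permeability; the enzyme kinetics are CYP3A4-mediated M14 and M11
    formation scaled to the whole liver.
    """
    return DrugParameters(
        fup=0.0645,
        blood_plasma_ratio=0.8,
        ka_per_min=0.0606,
        fa=0.761,
        fg=1.0,
        fu_mic=0.904,
        clu_add_ml_min=12.9e3,
        enzyme_pathways=[
            EnzymePathway(label="M14 (CYP3A4)", vmax_nmol_min=248.0, km_um=0.093),
            EnzymePathway(label="M11 (CYP3A4)", vmax_nmol_min=800.0, km_um=15.95),
        ],
        kp_map=dict(HUMAN_KP),
        pka=9.04,
        logp=2.38,
    )


#: Observed clinical NCA summaries used as fixed comparators for
#: prediction-ratio tables (group means; AUC_last in ng·min/mL, Cmax in
#: ng/mL).  ``n_doses``/``tau_h`` define the regimen to simulate and
#: ``window_h`` the (start, end) of the NCA window, hours after the first
#: dose.
OBSERVED_CLINICAL: tuple[dict, ...] = (
    {"set": "training (MAD day 1)", "dose_mg": 20, "n_doses": 1, "tau_h": 24.0,
     "window_h": (0.0, 24.0), "auc_obs": 9020.0, "cmax_obs": 16.3},
    {"set": "training (MAD day 1)", "dose_mg": 40, "n_doses": 1, "tau_h": 24.0,
     "window_h": (0.0, 24.0), "auc_obs": 23700.0, "cmax_obs": 40.4},
    {"set": "training (MAD day 1)", "dose_mg": 80, "n_doses": 1, "tau_h": 24.0,
     "window_h": (0.0, 24.0), "auc_obs": 62400.0, "cmax_obs": 99.1},
    {"set": "validation (MAD day 7)", "dose_mg": 20, "n_doses": 7, "tau_h": 24.0,
     "window_h": (144.0, 168.0), "auc_obs": 16300.0, "cmax_obs": 20.8},
    {"set": "validation (MAD day 7)", "dose_mg": 40, "n_doses": 7, "tau_h": 24.0,
     "window_h": (144.0, 168.0), "auc_obs": 28300.0, "cmax_obs": 43.2},
    {"set": "validation (MAD day 7)", "dose_mg": 80, "n_doses": 7, "tau_h": 24.0,
     "window_h": (144.0, 168.0), "auc_obs": 68700.0, "cmax_obs": 94.4},
    {"set": "validation (1st dose)", "dose_mg": 40, "n_doses": 1, "tau_h": 24.0,
     "window_h": (0.0, 48.0), "auc_obs": 21000.0, "cmax_obs": 28.8},
    {"set": "validation (1st dose)", "dose_mg": 80, "n_doses": 1, "tau_h": 24.0,
     "window_h": (0.0, 48.0), "auc_obs": 66300.0, "cmax_obs": 86.4},
    {"set": "validation (8th dose)", "dose_mg": 40, "n_doses": 8, "tau_h": 24.0,
     "window_h": (168.0, 216.0), "auc_obs": 28300.0, "cmax_obs": 35.5},
    {"set": "validation (8th dose)", "dose_mg": 80, "n_doses": 8, "tau_h": 24.0,
     "window_h": (168.0, 216.0), "auc_obs": 61800.0, "cmax_obs": 78.9},
)


# ---------------------------------------------------------------------------
# Config file I/O (YAML)
# ---------------------------------------------------------------------------

_PHYSIOLOGY_SCHEMA = "fexupk-physiology/1"
_DRUG_SCHEMA = "fexupk-drug/1"


def load_physiology(source: str | Path | dict | None = None) -> PhysiologySet:
    """Load a :class:`PhysiologySet` from a YAML file or dict.

    ``None`` returns the built-in reference physiology.
    """
    if source is None:
        return default_physiology()
    data = source if isinstance(source, dict) else _read_yaml(source)
    data = dict(data)
    data.pop("schema", None)
    tissues = data.pop("tissues")
    specs = [
        TissueSpec(
            name=name,
            drainage=spec.get("drainage", DEFAULT_DRAINAGE.get(name, "systemic-venous")),
            volume_ml=spec["volume_ml"],
            blood_flow_ml_min=spec["blood_flow_ml_min"],
            kp=spec.get("kp"),
        )
        for name, spec in tissues.items()
    ]
    return PhysiologySet(tissues=specs, **data)


def save_physiology(phys: PhysiologySet, path: str | Path) -> None:
    doc = {
        "schema": _PHYSIOLOGY_SCHEMA,
        "tissues": {
            t.name: {
                "volume_ml": t.volume_ml,
                "blood_flow_ml_min": t.blood_flow_ml_min,
                "drainage": t.drainage,
                **({"kp": t.kp} if t.kp is not None else {}),
            }
            for t in phys.tissues
        },
        "venous_blood_volume_ml": phys.venous_blood_volume_ml,
        "arterial_blood_volume_ml": phys.arterial_blood_volume_ml,
        "cardiac_output_ml_min": phys.cardiac_output_ml_min,
        "hematocrit": phys.hematocrit,
        "body_weight_kg": phys.body_weight_kg,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_drug_parameters(source: str | Path | dict | None = None) -> DrugParameters:
    """Load :class:`DrugParameters` from a YAML file or dict (None = built-in)."""
    if source is None:
        return default_drug_parameters()
    data = source if isinstance(source, dict) else _read_yaml(source)
    data = dict(data)
    data.pop("schema", None)
    return DrugParameters(**data)


def save_drug_parameters(drug: DrugParameters, path: str | Path) -> None:
    doc = {"schema": _DRUG_SCHEMA, **drug.model_dump()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# Concentration–time table I/O (CSV)
# ---------------------------------------------------------------------------

_CONC_COLUMNS = ["subject_id", "dose_mg", "time_min", "conc_ng_per_ml"]


def read_conc_table(path: str | Path) -> list[ConcTimeSeries]:
    """Read subject-level concentration–time records from CSV.

    Expected header: ``subject_id,dose_mg,time_min,conc_ng_per_ml`` with an
    optional ``day`` column.  Rows are grouped per subject; within a subject
    the times must already be sorted ascending (an out-of-order row raises,
    naming the offending row).
    """
    df = pd.read_csv(path)
    missing = [c for c in _CONC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) in {path}: {missing}")
    for col in ("dose_mg", "time_min", "conc_ng_per_ml"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad[0]) + 2  # +1 header, +1 zero-base
            raise ValueError(f"unparseable number in column {col!r}, row {row}")
    if "day" not in df.columns:
        df["day"] = 1
    out: list[ConcTimeSeries] = []
    for (sid, day), grp in df.groupby(["subject_id", "day"], sort=False):
        times = grp["time_min"].to_numpy()
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            pos = next(i for i in range(len(times) - 1) if times[i + 1] <= times[i])
            row = int(grp.index[pos + 1]) + 2
            raise ValueError(
                f"times not strictly increasing for subject {sid!r} at row {row}"
            )
        out.append(
            ConcTimeSeries(
                subject_id=str(sid),
                dose_mg=float(grp["dose_mg"].iloc[0]),
                times_min=[float(t) for t in times],
                conc_ng_ml=[float(c) for c in grp["conc_ng_per_ml"]],
                day=int(day),
            )
        )
    return out


def write_conc_table(series: Iterable[ConcTimeSeries], path: str | Path) -> None:
    """Write concentration–time records as CSV (lossless round trip)."""
    rows = []
    for s in series:
        for t, c in zip(s.times_min, s.conc_ng_ml):
            rows.append(
                {"subject_id": s.subject_id, "dose_mg": s.dose_mg,
                 "time_min": t, "conc_ng_per_ml": c, "day": s.day}
            )
    pd.DataFrame(rows, columns=_CONC_COLUMNS + ["day"]).to_csv(path, index=False)
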