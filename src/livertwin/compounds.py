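"""Compound physicochemistry: partitioning, permeability and cellular binding.

From three measured properties — lipophilicity (logP), molecular weight and
the unbound fraction in culture media — six downstream model parameters are
derived:

* three partition coefficients (media/interstitium, interstitium:water,
  cell:water) from Poulin–Theil-style tissue-composition partitioning,
* an endothelial permeability coefficient and the two membrane
  permeability–area products between interstitium and cell, from log-linear
  logP / inverse-power MW structure–permeability relations,
* the unbound intracellular fraction fu_cell from a hepatocyte-binding QSAR.

All constants live in :mod:`livertwin.constants`. The ionisation class
(-1 acid, 0 neutral, +1 base) shifts the effective logP used throughout by a
fixed per-class offset.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from . import constants
from .chips import ChipSpec

__all__ = [
    "CompoundRecord",
    "PartitionPermeabilitySet",
    "PARTITION_METHODS",
    "compute_partition_coefficients",
    "compute_permeabilities",
    "qsar_fu_cell",
    "compound_parameters",
    "effective_logp",
    "compounds_from_csv",
]

#: Partition-coefficient calculation methods exposed by the interface; only
#: poulin_theil is implemented, the others raise NotImplementedError.
PARTITION_METHODS = (
    "poulin_theil",
    "pk_sim_standard",
    "rodgers_rowland",
    "schmitt",
    "berezhkovskiy",
)

FU_CELL_MODELS = ("hepatocyte_binding", "microsome_binding")


class CompoundRecord(BaseModel):
    """Physicochemical identity of one compound."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str
    logp: float
    mw: float  # g/mol
    fu_media: float  # fraction in (0, 1]
    ionisation: int = 0  # -1 acid, 0 neutral, +1 base
    rbp: Optional[float] = None  # blood-to-plasma ratio
    fu_blood: Optional[float] = None  # measured, takes precedence in IVIVE

    @field_validator("mw")
    @classmethod
    def _mw(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("mw must be > 0")
        return v

    @field_validator("fu_media")
    @classmethod
    def _fu(cls, v: float) -> float:
        if not 0 < v <= 1:
            raise ValueError("fu_media must be in (0, 1]")
        return v

    @field_validator("ionisation")
    @classmethod
    def _ion(cls, v: int) -> int:
        if v not in (-1, 0, 1):
            raise ValueError("ionisation must be -1, 0 or +1")
        return v

    @field_validator("rbp")
    @classmethod
    def _rbp(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v <= 0:
            raise ValueError("rbp must be > 0 when given")
        return v


@dataclass(frozen=True)
class PartitionPermeabilitySet:
    """The six derived compound/chip parameters plus fu_cell."""

    k_int_med: float  # dimensionless
    k_water_int: float  # dimensionless
    k_water_cell: float  # dimensionless
    p_endothelial_cm_min: float
    pa_int_cell_ml_min: float
    pa_cell_int_ml_min: float
    fu_cell: float

    def __post_init__(self) -> None:
        if min(self.k_int_med, self.k_water_int, self.k_water_cell) <= 0:
            raise ValueError("partition coefficients must be > 0")
        if min(self.p_endothelial_cm_min, self.pa_int_cell_ml_min, self.pa_cell_int_ml_min) < 0:
            raise ValueError("permeabilities must be >= 0")
        if not 0 < self.fu_cell <= 1:
            raise ValueError("fu_cell must be in (0, 1]")


def effective_logp(compound: CompoundRecord) -> float:
    """logP shifted by the fixed per-ionisation-class offset."""
    return compound.logp + constants.IONISATION_LOGP_OFFSET[compound.ionisation]


def _tissue_water_partition(logp_eff: float, tissue: str) -> float:
    """Composition-based tissue:water partition coefficient.

    K = P*(V_nl + 0.3*V_ph) + (V_w + 0.7*V_ph) with P = 10**logP_eff;
    phospholipid behaves 30% lipid-like, 70% water-like.
    """
    comp = constants.TISSUE_COMPOSITION[tissue]
    p = 10.0 ** logp_eff
    return p * (comp["neutral_lipid"] + 0.3 * comp["phospholipid"]) + (
        comp["water"] + 0.7 * comp["phospholipid"]
    )


def compute_partition_coefficients(
    compound: CompoundRecord, method: str = "poulin_theil"
) -> tuple[float, float, float]:
    """(K_int_med, K_water_int, K_water_cell) for one compound.

    K_water_int and K_water_cell are interstitium:water and cell:water
    partition coefficients; K_int_med is their media-referenced counterpart
    (media treated as protein-free water, so K_int_med = K_water_int divided
    by the media:water coefficient, which is 1 for aqueous media).
    """
    if method not in PARTITION_METHODS:
        raise ValueError(
            f"unknown partition method {method!r}; available: {', '.join(PARTITION_METHODS)}"
        )
    if method != "poulin_theil":
        raise NotImplementedError(
            f"partition method {method!r} is not implemented; implemented: 'poulin_theil'"
        )
    lp = effective_logp(compound)
    k_water_int = _tissue_water_partition(lp, "interstitium")
    k_water_cell = _tissue_water_partition(lp, "cell")
    k_water_media = _tissue_water_partition(lp, "media")
    k_int_med = k_water_int / k_water_media
    return k_int_med, k_water_int, k_water_cell


def _permeability_cm_min(
    logp_eff: float, mw: float, p0: float, slope: float, mw_exp: float
) -> float:
    return p0 * 10.0 ** (slope * logp_eff) * (constants.MW_REF_G_MOL / mw) ** mw_exp


def compute_permeabilities(
    compound: CompoundRecord, chip: ChipSpec
) -> tuple[float, float, float]:
    """(P_endothelial [cm/min], PA_int_cell [mL/min], PA_cell_int [mL/min]).

    The endothelial coefficient is an areal permeability; the two PA products
    multiply the transcellular permeability by the aggregate hepatocyte
    membrane area of the chip (cell number x per-cell membrane area), so they
    scale linearly with that area. The same membrane bounds both directions,
    hence PA_int_cell = PA_cell_int; directional asymmetry of net transport
    comes from the partition coefficients in the rate constants, not from PA.
    """
    lp = effective_logp(compound)
    p_endo = _permeability_cm_min(
        lp,
        compound.mw,
        constants.ENDOTHELIAL_P0_CM_MIN,
        constants.ENDOTHELIAL_LOGP_SLOPE,
        constants.ENDOTHELIAL_MW_EXPONENT,
    )
    p_cell = _permeability_cm_min(
        lp,
        compound.mw,
        constants.TRANSCELLULAR_P0_CM_MIN,
        constants.TRANSCELLULAR_LOGP_SLOPE,
        constants.TRANSCELLULAR_MW_EXPONENT,
    )
    sa_cell = chip.cell_number * constants.PER_CELL_MEMBRANE_AREA_CM2
    pa = p_cell * sa_cell
    return p_endo, pa, pa


def qsar_fu_cell(compound: CompoundRecord, model: str = "hepatocyte_binding") -> float:
    """Unbound intracellular fraction predicted from logP and ionisation.

    fu_cell = 1 / (1 + C*VR*10**(A*L^2 + B*L + C0)) with L the effective
    logP; the quadratic argument is clamped at its vertex so the prediction
    is monotone non-increasing in logP (binding cannot increase as a compound
    becomes more hydrophilic).
    """
    if model not in FU_CELL_MODELS:
        raise ValueError(f"unknown fu_cell model {model!r}; available: {', '.join(FU_CELL_MODELS)}")
    if model != "hepatocyte_binding":
        raise NotImplementedError(
            f"fu_cell model {model!r} is not implemented; implemented: 'hepatocyte_binding'"
        )
    a, b, c = constants.FU_CELL_QUAD_A, constants.FU_CELL_QUAD_B, constants.FU_CELL_QUAD_C
    vertex = -b / (2.0 * a)
    lp = max(effective_logp(compound), vertex)
    binding = constants.FU_CELL_C_RATIO * constants.FU_CELL_VR * 10.0 ** (a * lp * lp + b * lp + c)
    return 1.0 / (1.0 + binding)


def compound_parameters(
    compound: CompoundRecord,
    chip: ChipSpec,
    partition_method: str = "poulin_theil",
    fu_cell_model: str = "hepatocyte_binding",
) -> PartitionPermeabilitySet:
    """Bundle all derived parameters for one compound on one chip."""
    k_int_med, k_water_int, k_water_cell = compute_partition_coefficients(
        compound, partition_method
    )
    p_endo, pa_ic, pa_ci = compute_permeabilities(compound, chip)
    fu_cell = qsar_fu_cell(compound, fu_cell_model)
    return PartitionPermeabilitySet(
        k_int_med=k_int_med,
        k_water_int=k_water_int,
        k_water_cell=k_water_cell,
        p_endothelial_cm_min=p_endo,
        pa_int_cell_ml_min=pa_ic,
        pa_cell_int_ml_min=pa_ci,
        fu_cell=fu_cell,
    )


def compounds_from_csv(path: str | Path) -> list[CompoundRecord]:
    """Read a compound table (columns: name, logp, mw, fu_media, ionisation,
    optionally rbp, fu_blood); one record per row."""
    df = pd.read_csv(path)
    records = []
    for row in df.to_dict(orient="records"):
        kwargs = {k: v for k, v in row.items() if not pd.isna(v)}
        if "ionisation" in kwargs:
            kwargs["ionisation"] = int(kwargs["ionisation"])
        records.append(CompoundRecord.model_validate(kwargs))
    return records
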