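"""Physiological and physicochemical constants used across the package.

Every tunable constant that feeds the compound-parameter calculations or the
human scale-up lives here, so a change of tissue composition or QSPR slope is
a one-line, auditable edit.

Units are encoded in the names: volumes in mL, areas in cm^2, permeabilities
in cm/min, clearances in mL/min unless stated otherwise.
"""

# --- cell geometry -----------------------------------------------------------
# Human hepatocyte volume ~3400 um^3; interstitial space taken as 20% of the
# aggregate cell volume. Both are overridable per chip.
PER_CELL_VOLUME_ML: float = 3.4e-9
INTERSTITIAL_VOLUME_FRACTION: float = 0.2
# Hepatocyte plasma-membrane area ~1100 um^2 per cell.
PER_CELL_MEMBRANE_AREA_CM2: float = 1.1e-5
# Nominal media/interstitium exchange area per cell (monolayer footprint).
PER_CELL_EXCHANGE_AREA_CM2: float = 1.0e-5

# --- tissue composition for Poulin-Theil-style partitioning ------------------
# Fractional volumes of water, neutral lipid and phospholipid.
# "interstitium" is treated as plasma-like, "cell" as liver-tissue-like,
# "media" as protein-free aqueous buffer (binding is carried by fu_media).
TISSUE_COMPOSITION: dict[str, dict[str, float]] = {
    "media": {"water": 1.000, "neutral_lipid": 0.0000, "phospholipid": 0.0000},
    "interstitium": {"water": 0.945, "neutral_lipid": 0.0023, "phospholipid": 0.0013},
    "cell": {"water": 0.751, "neutral_lipid": 0.0348, "phospholipid": 0.0252},
}

# Ionised molecules partition into neutral lipid less avidly than their logP
# suggests; the ionisation class shifts the effective logP by a fixed offset
# (acids are mostly ionised at pH 7.4, bases partially).
IONISATION_LOGP_OFFSET: dict[int, float] = {-1: -1.0, 0: 0.0, +1: -0.5}

# --- permeability QSPRs ------------------------------------------------------
# P = P0 * 10**(slope * logP_eff) * (MW_REF / MW)**mw_exponent  [cm/min]
MW_REF_G_MOL: float = 300.0
ENDOTHELIAL_P0_CM_MIN: float = 5.0e-3
ENDOTHELIAL_LOGP_SLOPE: float = 0.2
ENDOTHELIAL_MW_EXPONENT: float = 0.5
TRANSCELLULAR_P0_CM_MIN: float = 1.0e-3
TRANSCELLULAR_LOGP_SLOPE: float = 0.4
TRANSCELLULAR_MW_EXPONENT: float = 1.0

# --- intracellular unbound fraction QSAR -------------------------------------
# fu_cell = 1 / (1 + C_RATIO * VR * 10**(A*L^2 + B*L + C)), L = effective logP.
# Hepatocyte-binding form with a volume-ratio term; the quadratic argument is
# clamped at its vertex so fu_cell is monotone non-increasing in logP.
FU_CELL_VR: float = 0.005
FU_CELL_C_RATIO: float = 125.0
FU_CELL_QUAD_A: float = 0.072
FU_CELL_QUAD_B: float = 0.067
FU_CELL_QUAD_C: float = -1.126

# --- Kp_uu grid used when no observed Kp_uu is available ---------------------
KPUU_GRID: tuple[float, ...] = (0.1, 0.3, 1.0, 3.0, 10.0)
# Ionisation-class multiplier on the candidate Kp_uu grid: bases accumulate
# intracellularly (lysosomal trapping), acids are excluded.
KPUU_IONISATION_FACTOR: dict[int, float] = {-1: 0.5, 0: 1.0, +1: 3.0}

# --- human scale-up ----------------------------------------------------------
HC_CELLS_PER_G_LIVER: float = 120e6
LW_G_LIVER_PER_KG: float = 25.7
QH_ML_MIN_KG: float = 20.7
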