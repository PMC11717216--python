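"""In vitro – in vivo extrapolation of hepatic clearance.

The fitted on-chip intrinsic clearance (mL/min for the whole chip) is scaled
to a whole-liver unbound intrinsic clearance per kg body weight::

    CL_int(u),H = (CL_chip / N_cells) * HC * LW / fu_inc * SF

with hepatocellularity HC = 120e6 cells/g liver and liver weight
LW = 25.7 g/kg. SF is the compound-specific Kp_uu scaling factor (1 when no
observed Kp_uu informs it). Hepatic blood clearance then follows from the
well-stirred liver model::

    CL_H = Q_H * fu_b * CL_int(u),H / (Q_H + fu_b * CL_int(u),H)

bounded above by the hepatic blood flow Q_H = 20.7 mL/min/kg. fu_b is the
unbound fraction in blood, either measured or fu_p / Rbp.

For the digital-twin route, fu_inc defaults to 1 because the twin already
applies the media unbound fraction inside k1; for conventional
one-compartment fits fu_inc is the measured media unbound fraction. See the
methods note for the double-counting rationale.

Benchmark summaries (mean/SD/CV of predicted:observed ratios, average fold
error, fold-agreement fractions, a density curve for plotting) are produced
by :func:`prediction_summary`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import constants

__all__ = [
    "HumanScalingConstants",
    "ClearancePrediction",
    "PredictionSummary",
    "scale_to_human",
    "well_stirred",
    "fu_blood",
    "prediction_summary",
    "predictions_to_csv",
    "predictions_from_csv",
]


@dataclass(frozen=True)
class HumanScalingConstants:
    """Physiological scale-up constants (overridable defaults)."""

    hc_cells_per_g: float = constants.HC_CELLS_PER_G_LIVER
    lw_g_per_kg: float = constants.LW_G_LIVER_PER_KG
    qh_ml_min_kg: float = constants.QH_ML_MIN_KG

    def __post_init__(self) -> None:
        if min(self.hc_cells_per_g, self.lw_g_per_kg, self.qh_ml_min_kg) <= 0:
            raise ValueError("scaling constants must be > 0")


@dataclass(frozen=True)
class ClearancePrediction:
    """Per-compound human clearance prediction, optionally benchmarked."""

    compound: str
    cl_int_u_h: float  # mL/min/kg
    cl_h_pred: float  # mL/min/kg
    cl_h_obs: Optional[float] = None  # mL/min/kg
    method_tag: str = "digital_twin"  # or "conventional"

    @property
    def ratio(self) -> Optional[float]:
        if self.cl_h_obs is None:
            return None
        return self.cl_h_pred / self.cl_h_obs


@dataclass
class PredictionSummary:
    """Prediction-performance summary for one method."""

    method_tag: str
    n: int
    mean_ratio: float
    sd_ratio: float
    cv_percent: float
    afe: float
    frac_within_1_5: float
    frac_within_3: float
    kde_grid: np.ndarray = field(repr=False, default=None)
    kde_density: np.ndarray = field(repr=False, default=None)


def scale_to_human(
    cl_chip_ml_min: float,
    cell_number: float,
    fu_inc: float = 1.0,
    sf: float = 1.0,
    k: HumanScalingConstants = HumanScalingConstants(),
) -> float:
    """Whole-liver unbound intrinsic clearance, mL/min/kg body weight."""
    if cl_chip_ml_min < 0:
        raise ValueError("cl_chip_ml_min must be >= 0")
    if cell_number <= 0 or fu_inc <= 0 or sf <= 0:
        raise ValueError("cell_number, fu_inc and sf must be > 0")
    return cl_chip_ml_min / cell_number * k.hc_cells_per_g * k.lw_g_per_kg / fu_inc * sf


def well_stirred(
    cl_int_u_h: float,
    fu_b: float,
    k: HumanScalingConstants = HumanScalingConstants(),
) -> float:
    """Well-stirred hepatic clearance, mL/min/kg; strictly below Q_H."""
    if cl_int_u_h < 0 or fu_b < 0:
        raise ValueError("inputs must be >= 0")
    num = fu_b * cl_int_u_h
    return k.qh_ml_min_kg * num / (k.qh_ml_min_kg + num)


def fu_blood(fu_p: float, rbp: float, fu_b_measured: Optional[float] = None) -> float:
    """Unbound fraction in blood: measured value wins, else fu_p / Rbp."""
    if fu_b_measured is not None:
        if fu_b_measured <= 0:
            raise ValueError("measured fu_b must be > 0")
        return fu_b_measured
    if not 0 < fu_p <= 1:
        raise ValueError("fu_p must be in (0, 1]")
    if rbp <= 0:
        raise ValueError("rbp must be > 0")
    return fu_p / rbp


def prediction_summary(
    predictions: Sequence[ClearancePrediction],
    kde_points: int = 200,
) -> dict[str, PredictionSummary]:
    """Per-method benchmark summary of predicted:observed clearance ratios.

    AFE = 10**mean(log10 ratio); the fold-agreement fractions count compounds
    whose ratio (or its reciprocal) is within 1.5- and 3-fold of unity. The
    kernel-density curve of the ratios is attached for plotting only.
    """
    with_obs = [p for p in predictions if p.cl_h_obs is not None]
    if not with_obs:
        raise ValueError("prediction_summary needs at least one prediction with cl_h_obs")
    out: dict[str, PredictionSummary] = {}
    for tag in sorted({p.method_tag for p in with_obs}):
        ratios = np.array([p.ratio for p in with_obs if p.method_tag == tag])
        mean = float(np.mean(ratios))
        sd = float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0
        fold = np.maximum(ratios, 1.0 / ratios)
        grid = density = None
        if ratios.size > 1 and np.ptp(ratios) > 0:
            kde = stats.gaussian_kde(ratios)
            grid = np.linspace(0.0, float(ratios.max()) * 1.5, kde_points)
            density = kde(grid)
        out[tag] = PredictionSummary(
            method_tag=tag,
            n=int(ratios.size),
            mean_ratio=mean,
            sd_ratio=sd,
            cv_percent=100.0 * sd / mean if mean != 0 else float("nan"),
            afe=float(10.0 ** np.mean(np.log10(ratios))),
            frac_within_1_5=float(np.mean(fold <= 1.5)),
            frac_within_3=float(np.mean(fold <= 3.0)),
            kde_grid=grid,
            kde_density=density,
        )
    return out


def predictions_to_csv(predictions: Sequence[ClearancePrediction], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "compound": p.compound,
                "method_tag": p.method_tag,
                "cl_int_u_h_ml_min_kg": p.cl_int_u_h,
                "cl_h_pred_ml_min_kg": p.cl_h_pred,
                "cl_h_obs_ml_min_kg": p.cl_h_obs,
                "ratio": p.ratio,
            }
            for p in predictions
        ]
    ).to_csv(path, index=False)


def predictions_from_csv(path: str | Path) -> list[ClearancePrediction]:
    df = pd.read_csv(path)
    preds = []
    for row in df.to_dict(orient="records"):
        obs = row.get("cl_h_obs_ml_min_kg")
        preds.append(
            ClearancePrediction(
                compound=str(row["compound"]),
                cl_int_u_h=float(row["cl_int_u_h_ml_min_kg"]),
                cl_h_pred=float(row["cl_h_pred_ml_min_kg"]),
                cl_h_obs=None if obs is None or pd.isna(obs) else float(obs),
                method_tag=str(row.get("method_tag", "digital_twin")),
            )
        )
    return preds
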