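"""End-to-end panel workflows: fit every experiment, scale to human, summarise.

Glue used by the examples, the command-line interface and the acceptance
script; all substance lives in the per-step modules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .estimate import EstimationResult, FitOptions, fit_twin
from .ivive import (
    ClearancePrediction,
    PredictionSummary,
    fu_blood,
    prediction_summary,
    scale_to_human,
    well_stirred,
)
from .model import fit_one_compartment
from .synthetic import Panel, SyntheticExperiment

__all__ = ["PanelRun", "fit_experiment", "run_panel"]


def fit_experiment(
    exp: SyntheticExperiment, options: Optional[FitOptions] = None
) -> EstimationResult:
    """Digital-twin fit of one experiment's replicate-mean media series."""
    return fit_twin(
        exp.design.times_min,
        exp.observed_mean,
        exp.chip,
        exp.compound,
        kpuu_obs=exp.kpuu_obs,
        c0=exp.c0,
        options=options,
    )


@dataclass
class PanelRun:
    """Fits and human-clearance predictions for a whole panel."""

    panel: Panel
    fits: list[EstimationResult]
    predictions: list[ClearancePrediction]
    summaries: dict[str, PredictionSummary]


def run_panel(
    panel: Panel,
    options: Optional[FitOptions] = None,
    methods: Sequence[str] = ("digital_twin", "conventional"),
) -> PanelRun:
    """Fit every panel experiment and benchmark both extrapolation routes.

    The digital-twin route scales the fitted intrinsic clearance with the
    Kp_uu-derived scaling factor and fu_inc = 1 (media binding already acts
    inside k1); the conventional route scales the one-compartment lumped
    clearance with fu_inc = fu_media and SF = 1.
    """
    fits, predictions = [], []
    for exp in panel.experiments:
        fit = fit_experiment(exp, options)
        fits.append(fit)
        fu_b = fu_blood(exp.compound.fu_media, exp.compound.rbp, exp.compound.fu_blood)
        if "digital_twin" in methods:
            cl_int = scale_to_human(
                fit.cl_c_hat, exp.chip.cell_number, fu_inc=1.0, sf=fit.sf or 1.0
            )
            predictions.append(
                ClearancePrediction(
                    compound=exp.compound.name,
                    cl_int_u_h=cl_int,
                    cl_h_pred=well_stirred(cl_int, fu_b),
                    cl_h_obs=exp.cl_h_obs_ml_min_kg,
                    method_tag="digital_twin",
                )
            )
        if "conventional" in methods:
            conv = fit_one_compartment(
                exp.design.times_min, exp.observed_mean, exp.chip.media_volume_ml
            )
            cl_int = scale_to_human(
                max(conv.cl_c, 1e-12),
                exp.chip.cell_number,
                fu_inc=exp.compound.fu_media,
                sf=1.0,
            )
            predictions.append(
                ClearancePrediction(
                    compound=exp.compound.name,
                    cl_int_u_h=cl_int,
                    cl_h_pred=well_stirred(cl_int, fu_b),
                    cl_h_obs=exp.cl_h_obs_ml_min_kg,
                    method_tag="conventional",
                )
            )
    return PanelRun(
        panel=panel,
        fits=fits,
        predictions=predictions,
        summaries=prediction_summary(predictions),
    )
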