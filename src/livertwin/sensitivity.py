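"""Local and global (Sobol) sensitivity of intracellular exposure.

Nine inputs are varied: the three partition coefficients, the endothelial
permeability, the media/interstitium exchange area, the two membrane PA
products, the media unbound fraction and the intrinsic clearance. The output
functional is, by default, the AUC of the intracellular concentration over
the simulated window (the quantity the Kp_uu anchor consumes); a
single-time-point mode (C_c at the last grid time) is available.

Local indices are normalised forward differences, S_i = (dC/dP_i)(P_i/C),
evaluated at +10% perturbation by default (a central scheme is available).
Global first- and total-order indices use Sobol'-sequence sampling with
Saltelli-style estimators over [0.1x, 10x] of the baseline, with bootstrap
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chips import ChipSpec
from .compounds import CompoundRecord, compound_parameters
from .model import TwinParameters, propagate_eig_batch, simulation_grid, system_matrices

__all__ = [
    "SENSITIVITY_PARAMETERS",
    "TwinSensitivityProblem",
    "SensitivityReport",
    "local_sensitivity",
    "sobol_sensitivity",
    "sobol_indices_on",
]

SENSITIVITY_PARAMETERS = (
    "k_int_med",
    "p_endothelial",
    "sa_med_int_liver",
    "k_water_int",
    "k_water_cell",
    "pa_cell_int",
    "pa_int_cell",
    "fu",
    "cl_c",
)


class TwinSensitivityProblem:
    """Maps the nine named inputs onto the kinetic model and evaluates an
    output functional of the intracellular concentration, vectorised over
    parameter sets."""

    def __init__(
        self,
        chip: ChipSpec,
        compound: CompoundRecord,
        cl_c: float,
        c0_media: float = 1e-3,
        times: Optional[np.ndarray] = None,
        functional: str = "auc",
    ) -> None:
        if functional not in ("auc", "endpoint"):
            raise ValueError("functional must be 'auc' or 'endpoint'")
        pp = compound_parameters(compound, chip)
        sa = chip.sa_med_int_liver_cm2
        if sa is None:
            raise ValueError("chip needs a resolved sa_med_int_liver_cm2 for sensitivity analysis")
        self.baseline: dict[str, float] = {
            "k_int_med": pp.k_int_med,
            "p_endothelial": pp.p_endothelial_cm_min,
            "sa_med_int_liver": sa,
            "k_water_int": pp.k_water_int,
            "k_water_cell": pp.k_water_cell,
            "pa_cell_int": pp.pa_cell_int_ml_min,
            "pa_int_cell": pp.pa_int_cell_ml_min,
            "fu": compound.fu_media,
            "cl_c": cl_c,
        }
        self.functional = functional
        self.times = simulation_grid(360.0) if times is None else np.asarray(times, float)
        # geometry template; rate constants are overwritten per sample
        self.template = TwinParameters(
            k1=1.0,
            k2=1.0,
            k3=1.0,
            k4=1.0,
            cl_c=cl_c,
            v_m=chip.media_volume_ml,
            v_i=chip.v_interstitium_ml,
            v_c=chip.v_intracellular_ml,
            fu_media=compound.fu_media,
            n_media_chambers=chip.n_media_chambers,
            q_mix=chip.q_mix_ml_min if chip.n_media_chambers == 2 else 0.0,
        )
        self.c0_media = c0_media

    def evaluate_matrix(self, x: np.ndarray) -> np.ndarray:
        """Output for x of shape (9, N) ordered as SENSITIVITY_PARAMETERS."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        p = dict(zip(SENSITIVITY_PARAMETERS, x))
        k1 = p["fu"] * p["p_endothelial"] * p["sa_med_int_liver"]
        k2 = k1 / p["k_int_med"]
        k3 = p["k_water_int"] * p["pa_int_cell"]
        k4 = p["k_water_cell"] * p["pa_cell_int"]
        a = system_matrices(k1, k2, k3, k4, p["cl_c"], self.template)
        c0 = np.zeros(self.template.n_states)
        c0[: self.template.n_media_chambers] = self.c0_media
        states = propagate_eig_batch(a, c0, self.times)  # (N, T, n)
        c_c = states[:, :, -1]
        if self.functional == "endpoint":
            return c_c[:, -1]
        return np.trapezoid(c_c, self.times, axis=1)

    def evaluate(self, params: dict[str, float]) -> float:
        x = np.array([[params[name]] for name in SENSITIVITY_PARAMETERS])
        return float(self.evaluate_matrix(x)[0])


@dataclass
class SensitivityReport:
    """Tidy container for local and/or Sobol indices."""

    parameters: tuple[str, ...]
    local: Optional[dict[str, float]] = None
    sobol_first: Optional[dict[str, float]] = None
    sobol_total: Optional[dict[str, float]] = None
    sobol_first_ci: Optional[dict[str, tuple[float, float]]] = None
    sobol_total_ci: Optional[dict[str, tuple[float, float]]] = None
    n_samples: int = 0
    seed: Optional[int] = None
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.parameters:
            rows.append(
                {
                    "parameter": name,
                    "local_s": None if self.local is None else self.local.get(name),
                    "sobol_first": None if self.sobol_first is None else self.sobol_first[name],
                    "sobol_first_ci_low": None
                    if self.sobol_first_ci is None
                    else self.sobol_first_ci[name][0],
                    "sobol_first_ci_high": None
                    if self.sobol_first_ci is None
                    else self.sobol_first_ci[name][1],
                    "sobol_total": None if self.sobol_total is None else self.sobol_total[name],
                    "sobol_total_ci_low": None
                    if self.sobol_total_ci is None
                    else self.sobol_total_ci[name][0],
                    "sobol_total_ci_high": None
                    if self.sobol_total_ci is None
                    else self.sobol_total_ci[name][1],
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, ax=None):  # pragma: no cover - visual helper
        """Bar chart of local and Sobol indices (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        frame = self.to_frame().set_index("parameter")
        cols = [c for c in ("local_s", "sobol_first", "sobol_total") if frame[c].notna().any()]
        frame[cols].plot.bar(ax=ax)
        ax.set_ylabel("sensitivity index")
        return ax


def local_sensitivity(
    func: Callable[[dict[str, float]], float],
    baseline: dict[str, float],
    perturbation: float = 0.1,
    scheme: str = "forward",
) -> dict[str, float]:
    """One-at-a-time normalised sensitivity indices.

    S_i = (delta C / delta P_i) * (P_i / C) with delta P_i = perturbation*P_i.
    Sign is preserved: a negative index means the output falls when the input
    rises. Raises if the baseline output is zero (normalisation undefined).
    """
    if scheme not in ("forward", "central"):
        raise ValueError("scheme must be 'forward' or 'central'")
    y0 = func(baseline)
    if y0 == 0:
        raise ValueError("baseline output is zero; normalised index undefined")
    out: dict[str, float] = {}
    for name, p0 in baseline.items():
        hi = dict(baseline)
        hi[name] = p0 * (1.0 + perturbation)
        if scheme == "forward":
            dy = func(hi) - y0
            dp = p0 * perturbation
        else:
            lo = dict(baseline)
            lo[name] = p0 * (1.0 - perturbation)
            dy = func(hi) - func(lo)
            dp = 2.0 * p0 * perturbation
        out[name] = (dy / dp) * (p0 / y0) if p0 != 0 else 0.0
    return out


@dataclass
class _IndexCI:
    confidence_interval: "stats._resampling.ConfidenceInterval"


@dataclass
class _SobolBootstrap:
    first_order: _IndexCI
    total_order: _IndexCI


def _seeded_bootstrap(res, n_resamples: int, seed: Optional[int], confidence_level=0.95):
    """Percentile bootstrap of the Sobol indices with an explicit seed.

    Resamples the stored Saltelli sample columns (the estimator's own
    bootstrap scheme) so repeated runs with one seed give identical CIs.
    """

    def statistic(idx):
        return res._indices_method(res._f_A[:, idx], res._f_B[:, idx], res._f_AB[..., idx])

    n = res._f_A.shape[1]
    bres = stats.bootstrap(
        [np.arange(n)],
        statistic=statistic,
        method="percentile",
        n_resamples=n_resamples,
        confidence_level=confidence_level,
        rng=np.random.default_rng(seed),
    )
    ci = bres.confidence_interval
    CI = stats._resampling.ConfidenceInterval
    return _SobolBootstrap(
        first_order=_IndexCI(CI(ci.low[0], ci.high[0])),
        total_order=_IndexCI(CI(ci.low[1], ci.high[1])),
    )


def sobol_indices_on(
    func: Callable[[np.ndarray], np.ndarray],
    dists: Sequence,
    n: int,
    seed: Optional[int] = None,
    n_boot: int = 100,
):
    """Thin wrapper over the Sobol index estimator: returns the raw result
    and seeded bootstrap CIs for arbitrary input distributions (`func` takes
    an array of shape (d, n))."""
    res = stats.sobol_indices(func=func, n=n, dists=list(dists), rng=seed)
    boot = _seeded_bootstrap(res, n_boot, seed) if n_boot > 0 else None
    return res, boot


def sobol_sensitivity(
    problem: TwinSensitivityProblem,
    n_base: int = 1024,
    seed: Optional[int] = None,
    bounds_fold: tuple[float, float] = (0.1, 10.0),
    n_boot: int = 100,
) -> SensitivityReport:
    """First- and total-order Sobol indices of the output functional.

    Each input is sampled uniformly over [lo*baseline, hi*baseline]
    (default 0.1x to 10x). ``n_base`` must be a power of two (Sobol'
    sequence); values below 64 are accepted but flagged in the report.
    """
    if n_base & (n_base - 1) != 0:
        raise ValueError("n_base must be a power of 2")
    warnings_list: list[str] = []
    if n_base < 64:
        warnings_list.append(
            f"n_base={n_base} is small (< 64); Sobol index estimates will be noisy"
        )
    lo, hi = bounds_fold
    names = tuple(problem.baseline)
    dists = [
        stats.uniform(loc=lo * problem.baseline[k], scale=(hi - lo) * problem.baseline[k])
        for k in names
    ]
    res, boot = sobol_indices_on(problem.evaluate_matrix, dists, n_base, seed=seed, n_boot=n_boot)
    first = dict(zip(names, map(float, res.first_order)))
    total = dict(zip(names, map(float, res.total_order)))
    first_ci = total_ci = None
    if boot is not None:
        fci, tci = boot.first_order.confidence_interval, boot.total_order.confidence_interval
        first_ci = {k: (float(fci.low[i]), float(fci.high[i])) for i, k in enumerate(names)}
        total_ci = {k: (float(tci.low[i]), float(tci.high[i])) for i, k in enumerate(names)}
    return SensitivityReport(
        parameters=names,
        sobol_first=first,
        sobol_total=total,
        sobol_first_ci=first_ci,
        sobol_total_ci=total_ci,
        n_samples=n_base,
        seed=seed,
        warnings=warnings_list,
    )
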