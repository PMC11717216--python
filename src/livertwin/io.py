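"""CSV dialects for observed series and simulated trajectories.

Observed depletion series: columns ``time_min``, ``conc_umol_per_ml``,
optional ``compartment`` (default "media") and optional ``replicate``.
Trajectories are written tidy: ``time_min, compartment, conc_umol_per_ml``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .model import Trajectory

__all__ = ["read_observed_series", "write_observed_series", "write_trajectory", "read_trajectory"]


def read_observed_series(
    path: str | Path, compartment: str = "media"
) -> tuple[np.ndarray, np.ndarray]:
    """Read one depletion series; replicates are averaged per time point.

    Returns (times_min, conc_umol_per_ml) sorted by time.
    """
    df = pd.read_csv(path)
    missing = {"time_min", "conc_umol_per_ml"} - set(df.columns)
    if missing:
        raise ValueError(f"observed series {path} missing columns: {sorted(missing)}")
    if "compartment" in df.columns:
        df = df[df["compartment"] == compartment]
    if df.empty:
        raise ValueError(f"no rows for compartment {compartment!r} in {path}")
    grouped = df.groupby("time_min", sort=True)["conc_umol_per_ml"].mean()
    return grouped.index.to_numpy(dtype=float), grouped.to_numpy(dtype=float)


def write_observed_series(
    path: str | Path,
    times_min: np.ndarray,
    observed: np.ndarray,
    compartment: str = "media",
) -> None:
    """Write a (replicates, n_times) or (n_times,) series in the reader's dialect."""
    observed = np.atleast_2d(np.asarray(observed, dtype=float))
    rows = [
        {
            "time_min": t,
            "conc_umol_per_ml": observed[r, i],
            "compartment": compartment,
            "replicate": r,
        }
        for r in range(observed.shape[0])
        for i, t in enumerate(np.asarray(times_min, dtype=float))
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    frames = []
    for name, series in (("media", traj.c_m), ("interstitium", traj.c_i), ("intracellular", traj.c_c)):
        frames.append(
            pd.DataFrame(
                {"time_min": traj.times, "compartment": name, "conc_umol_per_ml": series}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectory(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
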