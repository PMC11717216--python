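"""Chip hardware library.

A liver-on-chip (or spheroid plate) is reduced to a set of well-mixed
compartments: one or two media chambers, an interstitial space and the
aggregate intracellular space of the seeded hepatocytes. The geometry needed
by the kinetic model is a handful of numbers: volumes, cell number, mixing
flow between media chambers and the media/interstitium exchange area.

Presets for the supported commercial systems ship as YAML files inside the
package; ``load_chip_preset`` resolves them by name.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from . import constants

__all__ = ["ChipSpec", "load_chip_preset", "available_presets", "PresetNotFoundError"]


class PresetNotFoundError(KeyError):
    """Raised when a chip preset name is not in the shipped library."""


class ChipSpec(BaseModel):
    """Geometry and cell loading of one chip architecture.

    Field names carry unit suffixes so serialised configs are self-describing.
    ``sa_med_int_liver_cm2`` may be ``None``, meaning the exchange area is left
    to the estimation step.
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    media_volume_ml: float
    cell_number: float
    n_media_chambers: int = 1
    recirculating: bool = False
    q_mix_ml_min: float = 0.0
    sa_med_int_liver_cm2: Optional[float] = None
    v_interstitium_ml: Optional[float] = None
    v_intracellular_ml: Optional[float] = None
    placeholder: bool = False

    @field_validator("media_volume_ml")
    @classmethod
    def _positive_media(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("media_volume_ml must be > 0")
        return v

    @field_validator("cell_number")
    @classmethod
    def _positive_cells(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("cell_number must be > 0")
        return v

    @field_validator("n_media_chambers")
    @classmethod
    def _chambers(cls, v: int) -> int:
        if v not in (1, 2):
            raise ValueError("n_media_chambers must be 1 or 2")
        return v

    @model_validator(mode="after")
    def _fill_and_check(self) -> "ChipSpec":
        if self.v_intracellular_ml is None:
            self.v_intracellular_ml = self.cell_number * constants.PER_CELL_VOLUME_ML
        if self.v_interstitium_ml is None:
            self.v_interstitium_ml = (
                constants.INTERSTITIAL_VOLUME_FRACTION * self.v_intracellular_ml
            )
        if self.v_intracellular_ml <= 0 or self.v_interstitium_ml <= 0:
            raise ValueError("compartment volumes must be > 0")
        if self.q_mix_ml_min < 0:
            raise ValueError("q_mix_ml_min must be >= 0")
        if self.recirculating != (self.q_mix_ml_min > 0):
            raise ValueError("q_mix_ml_min must be > 0 exactly when recirculating")
        if self.sa_med_int_liver_cm2 is not None and self.sa_med_int_liver_cm2 <= 0:
            raise ValueError("sa_med_int_liver_cm2 must be > 0 when given")
        return self

    # -- serialisation --------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ChipSpec":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


def available_presets() -> list[str]:
    """Names of the chip presets shipped with the package."""
    pkg = resources.files("livertwin") / "data" / "chips"
    return sorted(p.name.removesuffix(".yaml") for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_chip_preset(name: str) -> ChipSpec:
    """Load a shipped chip architecture by name.

    Raises
    ------
    PresetNotFoundError
        If ``name`` is not in the library; the message lists valid names.
    """
    pkg = resources.files("livertwin") / "data" / "chips" / f"{name}.yaml"
    if not pkg.is_file():
        raise PresetNotFoundError(
            f"preset not found: {name!r}; valid presets: {', '.join(available_presets())}"
        )
    spec = ChipSpec.model_validate(yaml.safe_load(pkg.read_text()))
    if spec.placeholder:
        warnings.warn(
            f"chip preset {name!r} ships placeholder geometry; override its fields "
            "with measured values before quantitative use",
            stacklevel=2,
        )
    return spec
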