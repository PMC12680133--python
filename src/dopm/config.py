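"""System configuration types and config-file loading.

The optical system is described by two :class:`ObjectiveSpec` objects (the
high-NA primary and the shared secondary/tertiary air lens), the oblique
illumination angle, and the measured double-pass transmission of the
polarizing beam splitter.  Every model in the package consumes a
:class:`SystemGeometry`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "ObjectiveSpec",
    "SystemGeometry",
    "default_system",
    "load_system",
]


@dataclass(frozen=True)
class ObjectiveSpec:
    """A microscope objective characterized by NA, immersion index and
    single-pass transmission."""

    na: float
    immersion_index: float
    single_pass_transmission: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.na <= self.immersion_index:
            raise ValueError(
                f"require 0 < na <= immersion index, got na={self.na}, "
                f"n={self.immersion_index}"
            )
        if not 0 <= self.single_pass_transmission <= 1:
            raise ValueError("single_pass_transmission must be in [0, 1]")


@dataclass(frozen=True)
class SystemGeometry:
    """Collection-path geometry of the dual-view system.

    Parameters
    ----------
    primary : ObjectiveSpec
        The sample-facing objective (O1).
    secondary_tertiary : ObjectiveSpec
        The air objective double-passed as O2 and O3.
    opm_angle_deg : float
        Angle of the light sheet with respect to the coverslip, degrees.
    t_pbs : float
        Measured double-pass PBS transmission for on-axis linearly
        polarized light.
    coating : str
        Name of the fold-mirror coating stack (see :mod:`dopm.coatings`).
    """

    primary: ObjectiveSpec
    secondary_tertiary: ObjectiveSpec
    opm_angle_deg: float = 35.0
    t_pbs: float = 0.8
    coating: str = "perfect"

    def __post_init__(self) -> None:
        if not 0 <= self.t_pbs <= 1:
            raise ValueError("t_pbs must be in [0, 1]")
        if not 0 <= self.opm_angle_deg < 90:
            raise ValueError(
                f"opm_angle_deg must be in [0, 90); got {self.opm_angle_deg}"
            )


def default_system(opm_angle_deg: float = 35.0, coating: str = "perfect") -> SystemGeometry:
    """The characterized instrument: 60x/1.2 NA water primary, 50x/0.95 air
    secondary/tertiary with 0.9 single-pass transmission, PBS double-pass 0.8."""
    return SystemGeometry(
        primary=ObjectiveSpec(na=1.2, immersion_index=1.333),
        secondary_tertiary=ObjectiveSpec(
            na=0.95, immersion_index=1.0, single_pass_transmission=0.9
        ),
        opm_angle_deg=opm_angle_deg,
        t_pbs=0.8,
        coating=coating,
    )


def _objective_from_dict(d: dict) -> ObjectiveSpec:
    return ObjectiveSpec(
        na=float(d["na"]),
        immersion_index=float(d.get("index", d.get("immersion_index", 1.0))),
        single_pass_transmission=float(d.get("transmission", 1.0)),
    )


def load_system(path: str | Path) -> SystemGeometry:
    """Load a :class:`SystemGeometry` from a YAML or JSON config file.

    Expected keys: ``objectives: {primary: {...}, secondary_tertiary: {...}}``,
    ``opm_angle_deg``, ``t_pbs``, ``coating``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    objs = cfg["objectives"]
    return SystemGeometry(
        primary=_objective_from_dict(objs["primary"]),
        secondary_tertiary=_objective_from_dict(objs["secondary_tertiary"]),
        opm_angle_deg=float(cfg.get("opm_angle_deg", 35.0)),
        t_pbs=float(cfg.get("t_pbs", 0.8)),
        coating=str(cfg.get("coating", "perfect")),
    )
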