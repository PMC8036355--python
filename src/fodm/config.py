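"""Run configuration: model parameters plus named unit selections.

A config is a small YAML document; every numeric parameter is echoed
verbatim into all outputs so a report is self-describing::

    scale: aggregate
    c: 9.0
    margin: 0.0
    K: 1.0
    interface_cutoff: 9.0
    units:
      complete:
        select: ["A", "B"]
        mode: individual
      dom1_in_complex:
        select: ["A:25-128"]
        mode: in_parent
        parent: complete

``mode: individual`` fits a fresh Gaussian field on the unit;
``mode: in_parent`` evaluates the unit as a fragment of the named parent
unit (the parent's field and profiles stand, renormalized over the
fragment).  Bundled example configs for the proteins commonly analyzed with
this model live under ``fodm/data/configs``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path

import yaml

from .field import DEFAULT_CUTOFF
from .scales import DEFAULT_SCALE, SCALES
from .structure import SelectionSpec


@dataclass
class UnitConfig:
    spec: SelectionSpec
    mode: str = "individual"            # individual | in_parent
    parent: str | None = None           # required for in_parent

    def __post_init__(self) -> None:
        if self.mode not in ("individual", "in_parent"):
            raise ValueError(f"unknown unit mode {self.mode!r}")
        if self.mode == "in_parent" and not self.parent:
            raise ValueError(f"unit {self.spec.name!r}: in_parent mode needs a parent")


@dataclass
class RunConfig:
    scale_name: str = DEFAULT_SCALE
    c: float = DEFAULT_CUTOFF
    margin: float = 0.0
    K: float = 1.0
    interface_cutoff: float = DEFAULT_CUTOFF
    units: dict[str, UnitConfig] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale_name not in SCALES:
            raise ValueError(
                f"unknown scale {self.scale_name!r}; available: {sorted(SCALES)}"
            )
        if self.c <= 0:
            raise ValueError("c must be positive")
        if self.K < 0:
            raise ValueError("K must be non-negative")
        for name, unit in self.units.items():
            if unit.mode == "in_parent" and unit.parent not in self.units:
                raise ValueError(
                    f"unit {name!r}: parent {unit.parent!r} is not a configured unit"
                )

    def echo(self) -> dict:
        """The parameter block embedded verbatim in every output."""
        return {
            "scale": self.scale_name,
            "c": self.c,
            "margin": self.margin,
            "K": self.K,
            "interface_cutoff": self.interface_cutoff,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        units: dict[str, UnitConfig] = {}
        for name, entry in (data.get("units") or {}).items():
            if isinstance(entry, list):  # shorthand: bare selection list
                entry = {"select": entry}
            units[name] = UnitConfig(
                spec=SelectionSpec.from_strings(name, entry["select"]),
                mode=entry.get("mode", "individual"),
                parent=entry.get("parent"),
            )
        return cls(
            scale_name=data.get("scale", DEFAULT_SCALE),
            c=float(data.get("c", DEFAULT_CUTOFF)),
            margin=float(data.get("margin", 0.0)),
            K=float(data.get("K", 1.0)),
            interface_cutoff=float(data.get("interface_cutoff", DEFAULT_CUTOFF)),
            units=units,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def bundled_config(name: str) -> RunConfig:
    """Load one of the example configs shipped with the package (e.g. '2vv5')."""
    ref = resources.files("fodm").joinpath(f"data/configs/{name.lower()}.yaml")
    if not ref.is_file():
        available = sorted(
            p.name.removesuffix(".yaml")
            for p in resources.files("fodm").joinpath("data/configs").iterdir()
        )
        raise FileNotFoundError(f"no bundled config {name!r}; available: {available}")
    return RunConfig.from_dict(yaml.safe_load(ref.read_text()))
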