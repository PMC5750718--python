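"""Configuration loading, validation, and the default constants table.

A :class:`RunConfig` bundles everything a pathway estimate depends on: the
stimulus, the anatomical parameters, the four density models, and the
reporting grains.  Defaults ship in ``data/defaults.yaml``; a user config
file (same YAML layout, any subset of keys) is merged over the defaults,
and unknown keys are rejected loudly rather than silently ignored.
"""

from __future__ import annotations

import copy
import io
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError
from .magnification import DensityAnchorTable, PowerLawModel, ShiftedParabolaModel
from .pathway import AnatomyParams, RoundingGrains, StimulusSpec

__all__ = ["ModelSet", "RunConfig", "default_config", "default_models", "load_defaults"]

_MODES = ("point", "integrated")


@dataclass(frozen=True)
class ModelSet:
    """The four density/magnification models of one pathway configuration."""

    cortical: PowerLawModel
    lgn_parvo: PowerLawModel
    lgn_magno: ShiftedParabolaModel
    rgc: DensityAnchorTable


@dataclass(frozen=True)
class RunConfig:
    """A fully validated set of inputs for one pathway estimate.

    Construct via :func:`default_config`, :meth:`from_dict`, or
    :meth:`from_yaml`; instances are immutable so sweeps cannot mutate a
    shared base configuration.
    """

    stimulus: StimulusSpec
    anatomy: AnatomyParams
    models: ModelSet
    rounding: RoundingGrains = field(default_factory=RoundingGrains)
    mode: str = "point"
    extrapolate_rgc: bool = False

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ConfigError(f"mode must be one of {_MODES}, got {self.mode!r}")

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        """Dump the effective configuration in the YAML file layout."""
        stim = self.stimulus
        m = self.models
        return {
            "stimulus": {
                "area": stim.area,
                "eccentricity": stim.eccentricity,
                "extent": list(stim.extent) if stim.extent is not None else None,
                "mode": self.mode,
            },
            "v1": {
                "magnification": {
                    "scale": m.cortical.scale,
                    "offset": m.cortical.offset,
                    "exponent": m.cortical.exponent,
                },
                "laminar_depth": self.anatomy.laminar_depth,
                "excitatory_fraction": self.anatomy.excitatory_fraction,
                "density": self.anatomy.v1_density,
                "tuned_fraction": self.anatomy.tuned_fraction,
                "responsive_fraction": self.anatomy.responsive_fraction,
            },
            "lgn": {
                "parvo": {
                    "scale": m.lgn_parvo.scale,
                    "offset": m.lgn_parvo.offset,
                    "exponent": m.lgn_parvo.exponent,
                },
                "magno": {
                    "scale": m.lgn_magno.scale,
                    "floor": m.lgn_magno.floor,
                    "center": m.lgn_magno.center,
                    "exponent": m.lgn_magno.exponent,
                },
            },
            "rgc": {
                "anchors": [list(a) for a in m.rgc.anchors],
                "extrapolate": self.extrapolate_rgc,
            },
            "rounding": {
                "surface": self.rounding.surface,
                "volume": self.rounding.volume,
                "v1": self.rounding.v1,
                "lgn": self.rounding.lgn,
                "rgc": self.rounding.rgc,
                "ratio": self.rounding.ratio,
            },
        }

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        """Build a config from a (possibly partial) dict merged over defaults."""
        merged = _merge(load_defaults(), data)
        return cls._from_full_dict(merged)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    @classmethod
    def _from_full_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        try:
            stim_d = d["stimulus"]
            v1_d = d["v1"]
            lgn_d = d["lgn"]
            rgc_d = d["rgc"]
            rnd_d = d["rounding"]
        except KeyError as exc:  # defaults always supply these
            raise ConfigError(f"missing config section {exc}") from exc
        extent = stim_d.get("extent")
        stimulus = StimulusSpec(
            area=stim_d["area"],
            eccentricity=stim_d["eccentricity"],
            extent=tuple(extent) if extent is not None else None,
        )
        anatomy = AnatomyParams(
            laminar_depth=v1_d["laminar_depth"],
            excitatory_fraction=v1_d["excitatory_fraction"],
            v1_density=v1_d["density"],
            tuned_fraction=v1_d["tuned_fraction"],
            responsive_fraction=v1_d["responsive_fraction"],
        )
        models = ModelSet(
            cortical=PowerLawModel(**v1_d["magnification"]),
            lgn_parvo=PowerLawModel(**lgn_d["parvo"]),
            lgn_magno=ShiftedParabolaModel(**lgn_d["magno"]),
            rgc=DensityAnchorTable(tuple(tuple(a) for a in rgc_d["anchors"])),
        )
        rounding = RoundingGrains(
            surface=rnd_d["surface"],
            volume=rnd_d["volume"],
            v1=rnd_d["v1"],
            lgn=rnd_d["lgn"],
            rgc=rnd_d["rgc"],
            ratio=rnd_d["ratio"],
        )
        return cls(
            stimulus=stimulus,
            anatomy=anatomy,
            models=models,
            rounding=rounding,
            mode=stim_d.get("mode", "point"),
            extrapolate_rgc=bool(rgc_d.get("extrapolate", False)),
        )

    # -- parameter paths (used by the sensitivity module and CLI) ---------

    def with_value(self, path: str, value: Any) -> "RunConfig":
        """Return a new config with the dotted parameter ``path`` replaced.

        Valid paths are the dotted keys of the YAML layout, e.g.
        ``stimulus.eccentricity``, ``v1.tuned_fraction``,
        ``v1.magnification.exponent``, ``rgc.extrapolate``.
        """
        d = self.to_dict()
        parts = path.split(".")
        node: Any = d
        for p in parts[:-1]:
            if not isinstance(node, dict) or p not in node:
                raise ConfigError(
                    f"unknown parameter path {path!r}; valid paths: "
                    + ", ".join(self.parameter_paths())
                )
            node = node[p]
        leaf = parts[-1]
        if not isinstance(node, dict) or leaf not in node:
            raise ConfigError(
                f"unknown parameter path {path!r}; valid paths: "
                + ", ".join(self.parameter_paths())
            )
        node[leaf] = value
        try:
            return RunConfig._from_full_dict(d)
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"invalid value {value!r} for {path!r}: {exc}") from exc

    def get_value(self, path: str) -> Any:
        d = self.to_dict()
        node: Any = d
        for p in path.split("."):
            if not isinstance(node, dict) or p not in node:
                raise ConfigError(
                    f"unknown parameter path {path!r}; valid paths: "
                    + ", ".join(self.parameter_paths())
                )
            node = node[p]
        return node

    def parameter_paths(self) -> list[str]:
        """All dotted leaf paths of the configuration."""
        out: list[str] = []

        def walk(node: Any, prefix: str) -> None:
            if isinstance(node, dict):
                for k, v in node.items():
                    walk(v, f"{prefix}{k}.")
            else:
                out.append(prefix[:-1])

        walk(self.to_dict(), "")
        return out


def _merge(base: dict[str, Any], override: Mapping[str, Any], prefix: str = "") -> dict[str, Any]:
    """Deep-merge ``override`` into a copy of ``base``, rejecting unknown keys.

    The anchor list is replaced wholesale rather than merged.
    """
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key not in out:
            raise ConfigError(f"unknown config key {prefix}{key}")
        if isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _merge(out[key], value, prefix=f"{prefix}{key}.")
        else:
            out[key] = value
    return out


@lru_cache(maxsize=1)
def _raw_defaults() -> dict[str, Any]:
    text = resources.files("vispop").joinpath("data/defaults.yaml").read_text()
    return yaml.safe_load(io.StringIO(text))


def load_defaults() -> dict[str, Any]:
    """The packaged default constants as a fresh nested dict."""
    return copy.deepcopy(_raw_defaults())


def default_config() -> RunConfig:
    """The default macaque configuration (1 deg^2 stimulus at 3 deg)."""
    return RunConfig._from_full_dict(load_defaults())


def default_models() -> ModelSet:
    """The default macaque density/magnification models."""
    return default_config().models
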