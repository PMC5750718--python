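"""Parameter sweeps and one-at-a-time sensitivity analyses.

The pathway estimate is a closed-form chain, so sensitivity analysis is an
exhaustive, deterministic grid evaluation — no sampling, no seeds.  Sweeps
never mutate the base configuration: each grid point is evaluated on an
immutable copy with one parameter replaced.

Output tables are pandas DataFrames with one column per stage quantity in
both raw and paper-rounded form, plus the expansion ratios, ready for CSV
export or plotting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Any, Mapping, Sequence

import pandas as pd

from .config import RunConfig
from .errors import ConfigError
from .pathway import PathwayEstimate, RatioReport, estimate_pathway

__all__ = ["SweepSpec", "sweep", "one_at_a_time", "estimate_record"]


@dataclass(frozen=True)
class SweepSpec:
    """A one-parameter grid sweep: a dotted config path and its values."""

    parameter: str
    grid: tuple[Any, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", tuple(self.grid))
        if len(self.grid) == 0:
            raise ConfigError(f"sweep grid for {self.parameter!r} is empty")


def estimate_record(config: RunConfig) -> dict[str, float]:
    """Flatten one pathway estimate into a single flat record.

    Stage fields appear as ``<name>_raw`` and ``<name>_rounded`` columns;
    ratio fields keep their names.  Undefined ratios (zero-area stimulus)
    are NaN.
    """
    est, ratios = estimate_pathway(
        config.stimulus,
        config.models,
        config.anatomy,
        grains=config.rounding,
        mode=config.mode,
        extrapolate_rgc=config.extrapolate_rgc,
    )
    rec: dict[str, float] = {}
    for f in fields(PathwayEstimate):
        if f.name == "stage_errors":
            continue
        value = getattr(est, f.name)
        rec[f"{f.name}_raw"] = value.raw
        rec[f"{f.name}_rounded"] = value.paper_rounded
    for f in fields(RatioReport):
        rec[f.name] = getattr(ratios, f.name) if ratios is not None else math.nan
    rec["stage_errors"] = "; ".join(est.stage_errors)
    return rec


def sweep(base_config: RunConfig, spec: SweepSpec) -> pd.DataFrame:
    """Evaluate the pathway estimate at every grid value of one parameter.

    All other parameters are held at the base configuration.  Every grid
    value is validated (by constructing its config) before any row is
    computed, so an invalid value fails the whole sweep up front.  Row
    order follows the grid.
    """
    configs = []
    for value in spec.grid:
        try:
            configs.append(base_config.with_value(spec.parameter, value))
        except ConfigError as exc:
            raise ConfigError(
                f"invalid grid value {value!r} for {spec.parameter!r}: {exc}"
            ) from exc
    rows = []
    for value, cfg in zip(spec.grid, configs):
        rec = {spec.parameter: value}
        rec.update(estimate_record(cfg))
        rows.append(rec)
    return pd.DataFrame(rows)


def one_at_a_time(
    base_config: RunConfig, perturbations: Mapping[str, float]
) -> pd.DataFrame:
    """Perturb each parameter by a relative delta, one at a time.

    ``perturbations`` maps dotted parameter paths to relative changes
    ``delta``; each parameter is evaluated at ``base * (1 - delta)`` and
    ``base * (1 + delta)`` with everything else held fixed.  The base row
    is included first.  A perturbation that leaves the parameter's domain
    produces a row with NaN outputs and the validation message in the
    ``error`` column; the remaining parameters are still computed.
    """
    rows: list[dict[str, Any]] = []
    base_rec: dict[str, Any] = {"parameter": "(base)", "side": "base", "value": math.nan}
    base_rec.update(estimate_record(base_config))
    base_rec["error"] = ""
    rows.append(base_rec)

    nan_outputs = {k: math.nan for k in base_rec if k not in ("parameter", "side", "value", "error", "stage_errors")}
    for path, delta in perturbations.items():
        base_value = base_config.get_value(path)
        if not isinstance(base_value, (int, float)) or isinstance(base_value, bool):
            raise ConfigError(f"cannot perturb non-numeric parameter {path!r}")
        for side, factor in (("low", 1 - delta), ("high", 1 + delta)):
            value = base_value * factor
            rec: dict[str, Any] = {"parameter": path, "side": side, "value": value}
            try:
                cfg = base_config.with_value(path, value)
            except ConfigError as exc:
                rec.update(nan_outputs)
                rec["stage_errors"] = ""
                rec["error"] = str(exc)
            else:
                rec.update(estimate_record(cfg))
                rec["error"] = ""
            rows.append(rec)
    return pd.DataFrame(rows)


def to_long(table: pd.DataFrame, id_column: str) -> pd.DataFrame:
    """Melt a sweep table to long format (grid value, output name, value)."""
    value_cols = [c for c in table.columns if c not in (id_column, "stage_errors", "error")]
    return table.melt(
        id_vars=[id_column], value_vars=value_cols, var_name="output", value_name="value"
    )
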