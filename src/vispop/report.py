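"""Plain-text and CSV rendering of pathway estimates."""

from __future__ import annotations

import math
from dataclasses import fields

import pandas as pd

from .config import RunConfig
from .pathway import PathwayEstimate, RatioReport
from .sensitivity import estimate_record

__all__ = ["render_report", "estimate_frame"]

_STAGE_LABELS = {
    "v1_surface": ("Cortical surface", "mm^2"),
    "v1_effective_depth": ("Effective depth", "mm"),
    "v1_volume": ("Effective volume", "mm^3"),
    "v1_upper": ("V1 upper bound", "neurons"),
    "v1_lower_tuned": ("V1 tuned lower bound", "neurons"),
    "v1_lower_loose": ("V1 loose lower bound", "neurons"),
    "lgn_parvo_count": ("LGN parvocellular", "cells"),
    "lgn_magno_count": ("LGN magnocellular", "cells"),
    "lgn_total_count": ("LGN total", "cells"),
    "rgc_count": ("RGC", "cells"),
}

_RATIO_LABELS = {
    "lgn_v1_low": "LGN:V1 low (loose lower bound)",
    "lgn_v1_high": "LGN:V1 high (upper bound)",
    "rgc_v1_low": "RGC:V1 low (loose lower bound)",
    "rgc_v1_high": "RGC:V1 high (upper bound)",
}


def _fmt(value: float) -> str:
    if math.isnan(value):
        return "n/a"
    return f"{value:,.6g}"


def render_report(
    est: PathwayEstimate,
    ratios: RatioReport | None,
    config: RunConfig,
    *,
    show_rounded: bool = True,
) -> str:
    """Human-readable report: stage table, ratios, and parameter provenance."""
    lines: list[str] = []
    stim = config.stimulus
    lines.append("Visual-pathway neuron count estimate")
    lines.append("=" * 36)
    lines.append(
        f"Stimulus: {stim.area:g} deg^2 at {stim.eccentricity:g} deg eccentricity "
        f"({config.mode} mode)"
    )
    lines.append("")
    header = f"{'stage':<26}{'raw':>16}"
    if show_rounded:
        header += f"{'rounded':>16}"
    header += "  units"
    lines.append(header)
    lines.append("-" * len(header))
    for name, (label, units) in _STAGE_LABELS.items():
        value = getattr(est, name)
        row = f"{label:<26}{_fmt(value.raw):>16}"
        if show_rounded:
            row += f"{_fmt(value.paper_rounded):>16}"
        row += f"  {units}"
        lines.append(row)
    lines.append("")
    if ratios is None:
        lines.append("Expansion ratios: undefined (a stage count is zero)")
    else:
        lines.append("Expansion ratios (rounded counts):")
        for name, label in _RATIO_LABELS.items():
            lines.append(f"  {label:<34}{_fmt(getattr(ratios, name)):>8} : 1")
    for err in est.stage_errors:
        lines.append(f"warning: stage not computed -- {err}")
    lines.append("")
    lines.append("Parameters:")
    for path in config.parameter_paths():
        lines.append(f"  {path} = {config.get_value(path)}")
    return "\n".join(lines) + "\n"


def estimate_frame(config: RunConfig) -> pd.DataFrame:
    """One-row DataFrame of the estimate, for CSV export."""
    rec = estimate_record(config)
    for path in config.parameter_paths():
        value = config.get_value(path)
        if isinstance(value, (int, float, str, bool)) or value is None:
            rec[f"param.{path}"] = value
    return pd.DataFrame([rec])


def field_names() -> list[str]:
    """The flat record's stage and ratio column names, in report order."""
    names = []
    for f in fields(PathwayEstimate):
        if f.name != "stage_errors":
            names += [f"{f.name}_raw", f"{f.name}_rounded"]
    names += [f.name for f in fields(RatioReport)]
    return names
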