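"""Per-stage neuron counts along the visual pathway and their bounds.

Given a stimulus (area and centre eccentricity) and a set of anatomical
assumptions, this module chains the density models into counts of neurons
engaged at each stage:

* **RGC** — stimulus area x interpolated retinal ganglion cell density.
* **LGN** — stimulus area x (parvocellular + magnocellular) cell
  magnification.
* **V1 upper bound** — cortical surface (area x areal magnification) x
  effective depth (projection-layer thickness x excitatory fraction) x
  volumetric neuron density.  "Upper" because it assumes every neuron in
  the activated volume informs the task.
* **V1 tuned lower bound** — upper bound x the fraction of neurons with
  orientation bandwidth under 30 deg (orientation-selective neurons only).
* **V1 loose lower bound** — additionally multiplied by the visually
  responsive fraction, discounting neurons silent throughout recordings.

Every count is carried twice: ``raw`` (full double precision) and
``paper_rounded``, a rounded-intermediate chain in which each stage is
rounded to a reporting grain *before* feeding the next stage.  The two
chains genuinely differ (the raw V1 upper bound is ~349,000 where the
rounded chain gives 360,000); reporting both keeps the headline figures
reproducible while exposing the honest full-precision estimate.  See
:class:`RoundingGrains` for the grains.

Expansion ratios (V1 count over upstream count) are defined from the
rounded counts, with the loose lower bound supplying the low end of each
range and the upper bound the high end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

from scipy import integrate

from .errors import ConfigError, DomainError, ExtrapolationError, UndefinedRatioError
from .magnification import DensityAnchorTable, PowerLawModel, ShiftedParabolaModel

__all__ = [
    "StimulusSpec",
    "AnatomyParams",
    "RoundingGrains",
    "StageValue",
    "PathwayEstimate",
    "RatioReport",
    "round_half_up",
    "round_paper_style",
    "cortical_surface",
    "effective_depth",
    "v1_upper",
    "v1_lower_tuned",
    "v1_lower_loose",
    "lgn_count",
    "rgc_count",
    "expansion_ratios",
    "estimate_pathway",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusSpec:
    """A visual stimulus: area in deg^2 centred at a given eccentricity.

    ``extent`` optionally gives (width, height) in deg for integrated-mode
    surface computation; it must be consistent with ``area``.  Eccentricity
    refers to the stimulus centre.
    """

    area: float
    eccentricity: float
    extent: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError(f"stimulus area must be >= 0 deg^2, got {self.area}")
        if self.eccentricity < 0:
            raise DomainError(f"eccentricity must be >= 0 deg, got {self.eccentricity}")
        if self.extent is not None:
            w, h = self.extent
            if w <= 0 or h <= 0:
                raise ValueError(f"extent must be positive, got {self.extent}")
            if abs(w * h - self.area) > 1e-9:
                raise ValueError(
                    f"extent {w} x {h} deg has area {w * h}, inconsistent "
                    f"with declared area {self.area} deg^2"
                )


@dataclass(frozen=True)
class AnatomyParams:
    """The configurable anatomical assumptions of the V1 estimate.

    Defaults are the macaque values: 0.75 mm of layer 2/3/4B depth, 80%
    excitatory neurons, 120,000 neurons/mm^3, 75% orientation-tuned
    (bandwidth < 30 deg), 55% visually responsive.
    """

    laminar_depth: float = 0.75
    excitatory_fraction: float = 0.8
    v1_density: float = 120_000.0
    tuned_fraction: float = 0.75
    responsive_fraction: float = 0.55

    def __post_init__(self) -> None:
        if self.laminar_depth <= 0:
            raise ValueError(f"laminar_depth must be > 0 mm, got {self.laminar_depth}")
        if self.v1_density <= 0:
            raise ValueError(f"v1_density must be > 0, got {self.v1_density}")
        for name in ("excitatory_fraction", "tuned_fraction", "responsive_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class RoundingGrains:
    """Reporting grains of the rounded-intermediate chain.

    The published figures are "approximately" values; these grains are the
    reporting resolution that reproduces them: surface and volume to 1 mm^2
    / 1 mm^3, V1 counts to 10,000, LGN counts to 1,000, RGC counts to 500,
    ratios to the nearest integer.  Rounding is half-up (148,500 -> 150,000).
    """

    surface: float = 1.0
    volume: float = 1.0
    v1: float = 10_000.0
    lgn: float = 1_000.0
    rgc: float = 500.0
    ratio: float = 1.0

    def __post_init__(self) -> None:
        for name in ("surface", "volume", "v1", "lgn", "rgc", "ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"rounding grain {name} must be > 0")


class StageValue(NamedTuple):
    """A stage quantity carried at full precision and at reporting grain."""

    raw: float
    paper_rounded: float


@dataclass(frozen=True)
class PathwayEstimate:
    """All per-stage quantities of one pathway estimate.

    Each field is a :class:`StageValue` (raw, paper_rounded).  ``stage_errors``
    records stages that could not be computed (currently only the RGC stage,
    when the eccentricity falls outside the anchor table); their values are
    NaN.
    """

    rgc_count: StageValue
    lgn_parvo_count: StageValue
    lgn_magno_count: StageValue
    lgn_total_count: StageValue
    v1_surface: StageValue
    v1_effective_depth: StageValue
    v1_volume: StageValue
    v1_upper: StageValue
    v1_lower_tuned: StageValue
    v1_lower_loose: StageValue
    stage_errors: tuple[str, ...] = field(default=())


@dataclass(frozen=True)
class RatioReport:
    """Expansion-ratio ranges, rounded counts over rounded counts.

    ``low`` divides the loose V1 lower bound by the upstream count; ``high``
    divides the V1 upper bound.  NaN marks a ratio whose upstream stage
    failed.
    """

    lgn_v1_low: float
    lgn_v1_high: float
    rgc_v1_low: float
    rgc_v1_high: float


# ---------------------------------------------------------------------------
# Rounding
# ---------------------------------------------------------------------------

_GRAIN_NAMES = ("surface", "volume", "v1", "lgn", "rgc", "ratio")


def round_half_up(value: float, grain: float) -> float:
    """Round ``value`` to the nearest multiple of ``grain``, ties away up.

    Python's ``round`` uses banker's rounding; the published chain needs
    148,500 -> 150,000, i.e. half-up.
    """
    if grain <= 0:
        raise ConfigError(f"rounding grain must be > 0, got {grain}")
    if math.isnan(value):
        return value
    return math.floor(value / grain + 0.5) * grain


def round_paper_style(
    value: float, grain: str, grains: RoundingGrains | None = None
) -> float:
    """Round a stage quantity to its reporting grain (half-up).

    ``grain`` names a stage: one of ``surface``, ``volume``, ``v1``,
    ``lgn``, ``rgc``, ``ratio``.
    """
    if value < 0:
        raise ValueError(f"cannot paper-round a negative value: {value}")
    if grain not in _GRAIN_NAMES:
        raise ConfigError(f"unknown rounding grain {grain!r}; expected one of {_GRAIN_NAMES}")
    grains = grains if grains is not None else RoundingGrains()
    return round_half_up(value, getattr(grains, grain))


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------


def cortical_surface(
    stim: StimulusSpec, model: PowerLawModel, mode: str = "point"
) -> float:
    """Cortical surface in mm^2 activated by the stimulus.

    ``point`` mode evaluates the magnification at the stimulus centre and
    multiplies by area — the convention of the original calculation.
    ``integrated`` mode treats the footprint as an eccentricity band of the
    stimulus height centred on E and integrates the magnification across
    it, weighted by stimulus width: surface = w * Int M(|e|) de over
    [E - h/2, E + h/2].  The absolute value mirrors the radial map across
    fixation for stimuli that straddle it.  The two modes converge as the
    extent shrinks.
    """
    if mode == "point":
        if stim.area == 0:
            return 0.0
        return stim.area * model(stim.eccentricity)
    if mode == "integrated":
        if stim.area == 0:
            return 0.0
        if stim.extent is not None:
            w, h = stim.extent
        else:
            w = h = math.sqrt(stim.area)
        lo, hi = stim.eccentricity - h / 2, stim.eccentricity + h / 2
        band, _ = integrate.quad(lambda e: model(abs(e)), lo, hi, limit=200)
        return w * band
    raise ConfigError(f"unknown surface mode {mode!r}; expected 'point' or 'integrated'")


def effective_depth(params: AnatomyParams) -> float:
    """Effective cortical depth in mm: projection-layer thickness times the
    excitatory fraction (0.8 x 0.75 mm = 0.6 mm at defaults)."""
    return params.laminar_depth * params.excitatory_fraction


def v1_upper(
    stim: StimulusSpec,
    model: PowerLawModel,
    params: AnatomyParams,
    mode: str = "point",
) -> float:
    """Raw (full-precision) V1 upper-bound count: surface x depth x density."""
    return cortical_surface(stim, model, mode) * effective_depth(params) * params.v1_density


def v1_lower_tuned(
    stim: StimulusSpec,
    model: PowerLawModel,
    params: AnatomyParams,
    mode: str = "point",
) -> float:
    """Raw tuned lower bound: tuned_fraction x upper bound."""
    return params.tuned_fraction * v1_upper(stim, model, params, mode)


def v1_lower_loose(
    stim: StimulusSpec,
    model: PowerLawModel,
    params: AnatomyParams,
    mode: str = "point",
) -> float:
    """Raw loose lower bound: tuned_fraction x responsive_fraction x upper."""
    return params.responsive_fraction * v1_lower_tuned(stim, model, params, mode)


def lgn_count(
    stim: StimulusSpec,
    parvo_model: PowerLawModel,
    magno_model: ShiftedParabolaModel,
) -> tuple[float, float, float]:
    """Raw LGN counts (parvo, magno, total) for the stimulus."""
    if stim.area == 0:
        return 0.0, 0.0, 0.0
    p = stim.area * parvo_model(stim.eccentricity)
    m = stim.area * magno_model(stim.eccentricity)
    return p, m, p + m


def rgc_count(
    stim: StimulusSpec,
    table: DensityAnchorTable,
    *,
    extrapolate: bool = False,
) -> float:
    """Raw RGC count: area x interpolated density.

    Raises :class:`~vispop.errors.ExtrapolationError` outside the anchor
    range unless ``extrapolate`` is set.
    """
    if stim.area == 0:
        return 0.0
    return stim.area * table(stim.eccentricity, extrapolate=extrapolate)


def expansion_ratios(
    est: PathwayEstimate, grains: RoundingGrains | None = None
) -> RatioReport:
    """Expansion-ratio ranges from the rounded counts of an estimate.

    Each ratio is (rounded V1 count) / (rounded upstream count), re-rounded
    to the nearest integer.  An upstream stage that failed (NaN) yields NaN
    ratios; a zero upstream count raises
    :class:`~vispop.errors.UndefinedRatioError`.
    """
    grains = grains if grains is not None else RoundingGrains()

    def pair(v1_low: float, v1_high: float, stage: float) -> tuple[float, float]:
        if math.isnan(stage):
            return math.nan, math.nan
        if stage == 0:
            raise UndefinedRatioError(
                "expansion ratio undefined: upstream stage count is zero"
            )
        return (
            round_half_up(v1_low / stage, grains.ratio),
            round_half_up(v1_high / stage, grains.ratio),
        )

    up = est.v1_upper.paper_rounded
    loose = est.v1_lower_loose.paper_rounded
    lgn_low, lgn_high = pair(loose, up, est.lgn_total_count.paper_rounded)
    rgc_low, rgc_high = pair(loose, up, est.rgc_count.paper_rounded)
    return RatioReport(
        lgn_v1_low=lgn_low,
        lgn_v1_high=lgn_high,
        rgc_v1_low=rgc_low,
        rgc_v1_high=rgc_high,
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def estimate_pathway(
    stim: StimulusSpec,
    models=None,
    params: AnatomyParams | None = None,
    *,
    grains: RoundingGrains | None = None,
    mode: str = "point",
    extrapolate_rgc: bool = False,
) -> tuple[PathwayEstimate, RatioReport | None]:
    """Run the full chain and return the estimate plus its ratio report.

    The raw chain carries full precision throughout.  The paper_rounded
    chain rounds each intermediate to its grain before the next stage:
    rounded surface -> volume -> rounded volume -> V1 upper -> rounded
    upper -> lower bounds.  Ratios are ``None`` when the stimulus area is
    zero (every count is zero, so no ratio is defined).

    ``models`` is a :class:`~vispop.config.ModelSet`; defaults to the
    macaque constants.
    """
    if models is None:
        from .config import default_models

        models = default_models()
    params = params if params is not None else AnatomyParams()
    grains = grains if grains is not None else RoundingGrains()
    errors: list[str] = []

    # V1 chain — raw.
    surface_raw = cortical_surface(stim, models.cortical, mode)
    depth = effective_depth(params)
    volume_raw = surface_raw * depth
    upper_raw = volume_raw * params.v1_density
    tuned_raw = params.tuned_fraction * upper_raw
    loose_raw = params.responsive_fraction * tuned_raw

    # V1 chain — rounded intermediates.
    surface_rnd = round_half_up(surface_raw, grains.surface)
    volume_rnd = round_half_up(surface_rnd * depth, grains.volume)
    upper_rnd = round_half_up(volume_rnd * params.v1_density, grains.v1)
    tuned_rnd = round_half_up(params.tuned_fraction * upper_rnd, grains.v1)
    loose_rnd = round_half_up(
        params.tuned_fraction * params.responsive_fraction * upper_rnd, grains.v1
    )

    # LGN.
    parvo_raw, magno_raw, lgn_raw = lgn_count(stim, models.lgn_parvo, models.lgn_magno)

    # RGC — may fail outside the anchor range; other stages still report.
    try:
        rgc_raw = rgc_count(stim, models.rgc, extrapolate=extrapolate_rgc)
    except ExtrapolationError as exc:
        rgc_raw = math.nan
        errors.append(f"rgc: {exc}")

    def sv(raw: float, grain: float) -> StageValue:
        return StageValue(raw, round_half_up(raw, grain) if not math.isnan(raw) else math.nan)

    est = PathwayEstimate(
        rgc_count=sv(rgc_raw, grains.rgc),
        lgn_parvo_count=sv(parvo_raw, grains.lgn),
        lgn_magno_count=sv(magno_raw, grains.lgn),
        lgn_total_count=sv(lgn_raw, grains.lgn),
        v1_surface=StageValue(surface_raw, surface_rnd),
        v1_effective_depth=StageValue(depth, depth),
        v1_volume=StageValue(volume_raw, volume_rnd),
        v1_upper=StageValue(upper_raw, upper_rnd),
        v1_lower_tuned=StageValue(tuned_raw, tuned_rnd),
        v1_lower_loose=StageValue(loose_raw, loose_rnd),
        stage_errors=tuple(errors),
    )

    if stim.area == 0:
        return est, None
    try:
        ratios = expansion_ratios(est, grains)
    except UndefinedRatioError:
        # a stage count rounded to zero at its reporting grain
        return est, None
    return est, ratios
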