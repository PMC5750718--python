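"""Closed-form areal density and magnification models of eccentricity.

The primate visual pathway allocates resources non-uniformly across the
visual field: the cortical surface devoted to one square degree of visual
field, and the density of subcortical cells feeding it, both fall steeply
with eccentricity.  This module provides the three closed-form models used
throughout the package —

* a power law ``a * (b + E)**(-c)`` for the V1 areal cortical magnification
  factor (mm^2 of cortex per deg^2 of visual field) and for the LGN
  parvocellular cell magnification (cells/deg^2);
* a shifted-parabola power law ``a * (b + (E - d)**2)**(-c)`` for the LGN
  magnocellular cell magnification, which peaks parafoveally rather than at
  fixation;
* piecewise-linear interpolation between tabulated retinal ganglion cell
  (RGC) densities at anchor eccentricities.

Model coefficients are data, not code: the macaque defaults ship in
``data/defaults.yaml`` and every public function accepts an explicit model,
so fits for other species (or other published magnification functions) can
be substituted without touching this module.

All eccentricities are radial distances from fixation in degrees of visual
angle; no meridian anisotropy is modelled.
"""

from __future__ import annotations

import logging
import numbers
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError, ExtrapolationError

__all__ = [
    "PowerLawModel",
    "ShiftedParabolaModel",
    "DensityAnchorTable",
    "cortical_magnification",
    "lgn_parvo_density",
    "lgn_magno_density",
    "rgc_density",
    "ECCENTRICITY_WARN_DEG",
]

logger = logging.getLogger(__name__)

#: The magnification fits come from parafoveal/peripheral data of unknown
#: extent; beyond this eccentricity we still evaluate but log a warning.
ECCENTRICITY_WARN_DEG = 20.0


def _check_eccentricity(E: float) -> float:
    """Validate a scalar eccentricity and return it as ``float``."""
    if not isinstance(E, numbers.Real) or isinstance(E, bool):
        raise DomainError(f"eccentricity must be a real number, got {E!r}")
    E = float(E)
    if not np.isfinite(E):
        raise DomainError(f"eccentricity must be finite, got {E}")
    if E < 0:
        raise DomainError(f"eccentricity must be >= 0 deg, got {E}")
    if E > ECCENTRICITY_WARN_DEG:
        logger.warning(
            "eccentricity %.3g deg exceeds %.0f deg; the magnification fits "
            "were derived from data of unknown peripheral extent",
            E,
            ECCENTRICITY_WARN_DEG,
        )
    return E


@dataclass(frozen=True)
class PowerLawModel:
    """Offset power law of eccentricity: ``scale * (offset + E)**(-exponent)``.

    Parameters
    ----------
    scale
        Multiplicative coefficient ``a`` (dimensionless; carries the output
        units).
    offset
        Additive eccentricity offset ``b`` in degrees.  A strictly positive
        offset keeps the value finite at fixation (E = 0).
    exponent
        Positive decay exponent ``c``; the value is strictly decreasing in E.
    """

    scale: float
    offset: float
    exponent: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if self.offset <= 0:
            raise ValueError(f"offset must be > 0, got {self.offset}")
        if self.exponent <= 0:
            raise ValueError(f"exponent must be > 0, got {self.exponent}")

    def __call__(self, E: float) -> float:
        E = _check_eccentricity(E)
        return self.scale * (self.offset + E) ** (-self.exponent)


@dataclass(frozen=True)
class ShiftedParabolaModel:
    """Power law of a shifted parabola:
    ``scale * (floor + (E - center)**2)**(-exponent)``.

    Unlike :class:`PowerLawModel` this is unimodal: the parabola in the base
    is minimised at ``E = center``, so the value peaks there and falls off
    symmetrically on either side.  It captures cell populations (the LGN
    magnocellular layers) whose density peaks parafoveally rather than at
    fixation.

    Parameters
    ----------
    scale
        Multiplicative coefficient ``a``.
    floor
        Positive parabola floor ``b`` in deg^2, keeping the base bounded
        away from zero.
    center
        Eccentricity ``d`` (deg) of the density peak.
    exponent
        Positive decay exponent ``c``.
    """

    scale: float
    floor: float
    center: float
    exponent: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if self.floor <= 0:
            raise ValueError(f"floor must be > 0, got {self.floor}")
        if self.exponent <= 0:
            raise ValueError(f"exponent must be > 0, got {self.exponent}")

    def __call__(self, E: float) -> float:
        E = _check_eccentricity(E)
        return self.scale * (self.floor + (E - self.center) ** 2) ** (-self.exponent)


@dataclass(frozen=True)
class DensityAnchorTable:
    """Tabulated (eccentricity, density) anchors for linear interpolation.

    Used for the RGC stage, where the literature reports densities at a few
    eccentricities rather than a fitted functional form.  Interpolation is
    exact at the anchors.  Queries outside the anchor range are refused by
    default — a two-point table gives no license to extrapolate — unless
    ``extrapolate=True`` is passed, in which case the nearest segment is
    extended linearly and a warning is logged.
    """

    anchors: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        anchors = tuple((float(e), float(d)) for e, d in self.anchors)
        object.__setattr__(self, "anchors", anchors)
        if len(anchors) < 2:
            raise ValueError("anchor table needs at least 2 anchors")
        eccs = [e for e, _ in anchors]
        if any(b <= a for a, b in zip(eccs, eccs[1:])):
            raise ValueError(f"anchor eccentricities must be strictly increasing, got {eccs}")
        if any(d <= 0 for _, d in anchors):
            raise ValueError("anchor densities must be > 0")

    @property
    def eccentricities(self) -> np.ndarray:
        return np.array([e for e, _ in self.anchors])

    @property
    def densities(self) -> np.ndarray:
        return np.array([d for _, d in self.anchors])

    @property
    def range(self) -> tuple[float, float]:
        """(min, max) anchor eccentricity in degrees."""
        return self.anchors[0][0], self.anchors[-1][0]

    def __call__(self, E: float, *, extrapolate: bool = False) -> float:
        E = _check_eccentricity(E)
        lo, hi = self.range
        if not lo <= E <= hi:
            if not extrapolate:
                raise ExtrapolationError(
                    f"eccentricity {E} deg is outside the anchor range "
                    f"[{lo}, {hi}] deg; pass extrapolate=True to extend the "
                    "nearest segment linearly"
                )
            logger.warning(
                "extrapolating anchor table linearly to %.3g deg, outside "
                "the tabulated range [%.3g, %.3g] deg",
                E,
                lo,
                hi,
            )
            # np.interp clamps, so extend the end segment by hand.
            eccs, dens = self.eccentricities, self.densities
            if E < lo:
                i0, i1 = 0, 1
            else:
                i0, i1 = -2, -1
            slope = (dens[i1] - dens[i0]) / (eccs[i1] - eccs[i0])
            return float(dens[i1] + slope * (E - eccs[i1]))
        return float(np.interp(E, self.eccentricities, self.densities))


def cortical_magnification(E: float, model: PowerLawModel | None = None) -> float:
    """Areal cortical magnification factor M(E) in mm^2/deg^2.

    With the default macaque V1 model this is ``103 * (0.82 + E)**(-2.28)``:
    about 162 mm^2/deg^2 at fixation, falling below 5 mm^2/deg^2 by 3 deg.
    """
    if model is None:
        from .config import default_models

        model = default_models().cortical
    return model(E)


def lgn_parvo_density(E: float, model: PowerLawModel | None = None) -> float:
    """LGN parvocellular cell magnification N_P(E) in cells/deg^2."""
    if model is None:
        from .config import default_models

        model = default_models().lgn_parvo
    return model(E)


def lgn_magno_density(E: float, model: ShiftedParabolaModel | None = None) -> float:
    """LGN magnocellular cell magnification N_M(E) in cells/deg^2.

    Unimodal with its peak at ``model.center`` (1.83 deg for the default
    macaque fit), unlike the monotonically decreasing parvocellular model.
    """
    if model is None:
        from .config import default_models

        model = default_models().lgn_magno
    return model(E)


def rgc_density(
    E: float,
    table: DensityAnchorTable | Sequence[tuple[float, float]] | None = None,
    *,
    extrapolate: bool = False,
) -> float:
    """Retinal ganglion cell density in cells/deg^2 by linear interpolation.

    The default table anchors 8,500 cells/deg^2 at 2 deg and 3,000 cells/deg^2
    at 5 deg (counts already folded for binocular viewing and the ~90%
    RGC-to-LGN projection fraction, as in the source tabulation).

    Raises
    ------
    ExtrapolationError
        If ``E`` lies outside the anchor range and ``extrapolate`` is False.
    """
    if table is None:
        from .config import default_models

        table = default_models().rgc
    elif not isinstance(table, DensityAnchorTable):
        table = DensityAnchorTable(tuple(table))
    return table(E, extrapolate=extrapolate)
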