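"""Pathway counts: the worked example, rounding, bounds, and linearity."""

import math
from dataclasses import fields

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vispop import (
    AnatomyParams,
    ConfigError,
    ExtrapolationError,
    PathwayEstimate,
    RoundingGrains,
    StimulusSpec,
    UndefinedRatioError,
    cortical_surface,
    effective_depth,
    estimate_pathway,
    expansion_ratios,
    lgn_count,
    rgc_count,
    round_half_up,
    round_paper_style,
    v1_lower_loose,
    v1_lower_tuned,
    v1_upper,
)

DEFAULT_STIM = StimulusSpec(area=1.0, eccentricity=3.0)


# ---------------------------------------------------------------------------
# Stimulus / parameter validation
# ---------------------------------------------------------------------------


def test_stimulus_extent_must_match_area():
    StimulusSpec(area=2.0, eccentricity=3.0, extent=(1.0, 2.0))  # consistent
    with pytest.raises(ValueError, match="inconsistent"):
        StimulusSpec(area=1.0, eccentricity=3.0, extent=(1.0, 2.0))


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(laminar_depth=-0.75),
        dict(excitatory_fraction=1.2),
        dict(tuned_fraction=-0.1),
        dict(v1_density=0.0),
    ],
)
def test_anatomy_invariants_enforced(kwargs):
    with pytest.raises(ValueError):
        AnatomyParams(**kwargs)


# ---------------------------------------------------------------------------
# Rounding convention
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "value, grain, expected",
    [
        (148_500, "v1", 150_000),  # half rounds up
        (144_042.02, "v1", 140_000),
        (9_195.06, "lgn", 9_000),
        (6_666.67, "rgc", 6_500),
        (4.8499, "surface", 5.0),
        (2.9099, "volume", 3.0),
        (16.6667, "ratio", 17.0),
        (55.3846, "ratio", 55.0),
    ],
)
def test_round_paper_style(value, grain, expected):
    assert round_paper_style(value, grain) == expected


@settings(derandomize=True, max_examples=200)
@given(
    value=st.floats(min_value=0, max_value=1e7, allow_nan=False),
    grain=st.sampled_from([1.0, 500.0, 1000.0, 10000.0]),
)
def test_rounding_idempotent_and_within_half_grain(value, grain):
    r = round_half_up(value, grain)
    assert round_half_up(r, grain) == r
    assert abs(r - value) <= grain / 2


def test_unknown_grain_rejected():
    with pytest.raises(ConfigError, match="grain"):
        round_paper_style(100.0, "furlongs")


# ---------------------------------------------------------------------------
# Individual stages (defaults = macaque worked example)
# ---------------------------------------------------------------------------


def test_cortical_surface_point(models):
    s = cortical_surface(DEFAULT_STIM, models.cortical)
    assert s == pytest.approx(4.849899701631094, rel=1e-12)
    assert cortical_surface(StimulusSpec(0.0, 7.0), models.cortical) == 0.0


def test_cortical_surface_unknown_mode(models):
    with pytest.raises(ConfigError, match="mode"):
        cortical_surface(DEFAULT_STIM, models.cortical, mode="banded")


def test_integrated_mode_close_to_point_and_converges(models):
    point = cortical_surface(DEFAULT_STIM, models.cortical, "point")
    integ = cortical_surface(
        StimulusSpec(1.0, 3.0, extent=(1.0, 1.0)), models.cortical, "integrated"
    )
    assert integ == pytest.approx(point, rel=0.05)
    # Riemann-sum oracle over the 1-deg band at 10^4 subdivisions
    import numpy as np

    edges = np.linspace(2.5, 3.5, 10_001)
    mids = (edges[:-1] + edges[1:]) / 2
    riemann = float(np.sum(models.cortical.scale * (models.cortical.offset + mids) ** (-models.cortical.exponent)) * (edges[1] - edges[0]))
    assert integ == pytest.approx(riemann, rel=1e-8)
    # shrinking extent -> point evaluation
    eps = 1e-4
    tiny = cortical_surface(
        StimulusSpec(eps * eps, 3.0, extent=(eps, eps)), models.cortical, "integrated"
    )
    assert tiny / (eps * eps) == pytest.approx(point, rel=1e-6)


def test_effective_depth_defaults_and_identity():
    assert effective_depth(AnatomyParams()) == pytest.approx(0.6)
    assert effective_depth(AnatomyParams(excitatory_fraction=1.0)) == pytest.approx(0.75)
    assert effective_depth(
        AnatomyParams(laminar_depth=1.0, excitatory_fraction=0.5)
    ) == pytest.approx(0.5)


def test_v1_bounds_raw_chain(models):
    p = AnatomyParams()
    up = v1_upper(DEFAULT_STIM, models.cortical, p)
    assert up == pytest.approx(4.849899701631094 * 0.6 * 120_000, rel=1e-9)
    assert v1_lower_tuned(DEFAULT_STIM, models.cortical, p) == pytest.approx(0.75 * up)
    assert v1_lower_loose(DEFAULT_STIM, models.cortical, p) == pytest.approx(0.75 * 0.55 * up)
    # identities at degenerate fractions
    p1 = AnatomyParams(tuned_fraction=1.0, responsive_fraction=1.0)
    assert v1_lower_tuned(DEFAULT_STIM, models.cortical, p1) == pytest.approx(
        v1_upper(DEFAULT_STIM, models.cortical, p1)
    )
    p0 = AnatomyParams(tuned_fraction=0.0)
    assert v1_lower_tuned(DEFAULT_STIM, models.cortical, p0) == 0.0


def test_lgn_and_rgc_counts(models):
    p, m, total = lgn_count(DEFAULT_STIM, models.lgn_parvo, models.lgn_magno)
    assert total == pytest.approx(9195.062387152553, rel=1e-12)
    assert total == p + m
    assert lgn_count(StimulusSpec(0.0, 3.0), models.lgn_parvo, models.lgn_magno) == (0, 0, 0)
    assert rgc_count(DEFAULT_STIM, models.rgc) == pytest.approx(6500 + 500 / 3)
    assert rgc_count(StimulusSpec(1.0, 2.0), models.rgc) == pytest.approx(8500.0)
    with pytest.raises(ExtrapolationError):
        rgc_count(StimulusSpec(1.0, 10.0), models.rgc)


# ---------------------------------------------------------------------------
# Full estimate: the worked example and its invariants
# ---------------------------------------------------------------------------


def test_default_estimate_reproduces_rounded_figures(models):
    est, ratios = estimate_pathway(DEFAULT_STIM, models)
    assert est.v1_surface.paper_rounded == 5.0
    assert est.v1_effective_depth.raw == pytest.approx(0.6)
    assert est.v1_volume.paper_rounded == 3.0
    assert est.v1_upper.paper_rounded == 360_000
    assert est.v1_lower_tuned.paper_rounded == 270_000
    assert est.v1_lower_loose.paper_rounded == 150_000
    assert est.lgn_total_count.paper_rounded == 9_000
    assert est.rgc_count.paper_rounded == 6_500
    assert (ratios.lgn_v1_low, ratios.lgn_v1_high) == (17, 40)
    assert (ratios.rgc_v1_low, ratios.rgc_v1_high) == (23, 55)


def test_raw_chain_differs_from_rounded_chain(models):
    """The honest full-precision upper bound (~349,000) is reported alongside
    the rounded-intermediate figure (360,000)."""
    est, _ = estimate_pathway(DEFAULT_STIM, models)
    assert est.v1_upper.raw == pytest.approx(349_192.8, rel=1e-4)
    assert est.v1_upper.raw != est.v1_upper.paper_rounded
    assert round_half_up(est.v1_surface.raw, 1.0) * 0.6 * 120_000 == pytest.approx(360_000)


@settings(derandomize=True, max_examples=100)
@given(
    tuned=st.floats(min_value=0, max_value=1, allow_nan=False),
    responsive=st.floats(min_value=0, max_value=1, allow_nan=False),
)
def test_bound_ordering(models, tuned, responsive):
    p = AnatomyParams(tuned_fraction=tuned, responsive_fraction=responsive)
    est, _ = estimate_pathway(DEFAULT_STIM, models, p)
    assert est.v1_lower_loose.raw <= est.v1_lower_tuned.raw <= est.v1_upper.raw
    assert (
        est.v1_lower_loose.paper_rounded
        <= est.v1_lower_tuned.paper_rounded
        <= est.v1_upper.paper_rounded
    )


@settings(derandomize=True, max_examples=100)
@given(
    area=st.floats(min_value=1e-3, max_value=10, allow_nan=False),
    scale=st.floats(min_value=0.5, max_value=4, allow_nan=False),
)
def test_raw_counts_linear_in_area(models, area, scale):
    est1, _ = estimate_pathway(StimulusSpec(area, 3.0), models)
    est2, _ = estimate_pathway(StimulusSpec(area * scale, 3.0), models)
    for name in ("rgc_count", "lgn_total_count", "v1_upper", "v1_lower_loose"):
        assert getattr(est2, name).raw == pytest.approx(
            scale * getattr(est1, name).raw, rel=1e-9
        )


def test_rounding_consistency_of_noncascaded_fields(models):
    """Non-cascaded rounded fields equal round_half_up(raw) at their grain."""
    est, _ = estimate_pathway(DEFAULT_STIM, models)
    g = RoundingGrains()
    assert est.rgc_count.paper_rounded == round_half_up(est.rgc_count.raw, g.rgc)
    assert est.lgn_total_count.paper_rounded == round_half_up(est.lgn_total_count.raw, g.lgn)
    assert est.v1_surface.paper_rounded == round_half_up(est.v1_surface.raw, g.surface)


def test_ratios_recomputed_from_rounded_counts(models):
    est, ratios = estimate_pathway(DEFAULT_STIM, models)
    assert ratios.lgn_v1_high == round_half_up(
        est.v1_upper.paper_rounded / est.lgn_total_count.paper_rounded, 1.0
    )
    assert ratios.rgc_v1_low == round_half_up(
        est.v1_lower_loose.paper_rounded / est.rgc_count.paper_rounded, 1.0
    )


def test_zero_area_all_zero_and_ratios_undefined(models):
    est, ratios = estimate_pathway(StimulusSpec(0.0, 3.0), models)
    for f in fields(PathwayEstimate):
        if f.name in ("stage_errors", "v1_effective_depth"):
            continue
        assert getattr(est, f.name).raw == 0.0
    assert ratios is None
    with pytest.raises(UndefinedRatioError):
        expansion_ratios(est)


def test_rgc_out_of_range_reports_other_stages(models):
    est, ratios = estimate_pathway(StimulusSpec(1.0, 10.0), models)
    assert math.isnan(est.rgc_count.raw)
    assert est.stage_errors and "anchor range" in est.stage_errors[0]
    assert est.v1_upper.raw > 0 and est.lgn_total_count.raw > 0
    assert math.isnan(ratios.rgc_v1_low) and not math.isnan(ratios.lgn_v1_low)


def test_doubling_density_scales_only_v1(models):
    base, _ = estimate_pathway(DEFAULT_STIM, models, AnatomyParams())
    dbl, _ = estimate_pathway(DEFAULT_STIM, models, AnatomyParams(v1_density=240_000))
    for name in ("v1_upper", "v1_lower_tuned", "v1_lower_loose"):
        assert getattr(dbl, name).raw == pytest.approx(2 * getattr(base, name).raw)
    assert dbl.rgc_count.raw == base.rgc_count.raw
    assert dbl.lgn_total_count.raw == base.lgn_total_count.raw


def test_determinism_byte_identical_reports(config):
    from vispop.report import render_report
    from vispop.pathway import estimate_pathway

    out = []
    for _ in range(2):
        est, ratios = estimate_pathway(
            config.stimulus, config.models, config.anatomy, grains=config.rounding
        )
        out.append(render_report(est, ratios, config))
    assert out[0] == out[1]
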