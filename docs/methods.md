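# Methods

## The calculation

`vispop` estimates neuron counts at three stages of the primate (macaque)
visual pathway for a stimulus of area *A* deg² centred at eccentricity *E*
deg. The chain is entirely closed-form — no fitting, no sampling — so the
package's job is careful bookkeeping: validated parameters, explicit units,
and a reproducible reporting convention.

**V1.** The areal cortical magnification factor

> M(E) = 103 (0.82 + E)^−2.28  [mm²/deg²]

maps stimulus area to activated cortical surface S = A·M(E). Depth is
restricted to the layers whose pyramidal neurons project to higher cortex
(2/3/4B, 0.75 mm), scaled by the excitatory fraction (0.8) to an effective
depth of 0.6 mm. Volume times volumetric density (120,000 neurons/mm³)
gives the **upper bound**: every neuron in the activated volume counted as
potentially task-relevant. The **tuned lower bound** keeps only neurons
with orientation bandwidth below 30° (fraction 0.75 across those layers);
the **loose lower bound** additionally discounts neurons silent throughout
a recording session via the visually-responsive fraction (0.55, from
calcium-imaging population censuses, which do not share the responsiveness
bias of electrode sampling).

**LGN.** Parvocellular and magnocellular cell magnification factors
(cells/deg²):

> N_P(E) = 1,011,688 (2.9144 + E)^−2.6798
> N_M(E) = 2,620.2 (5.5638 + (E − 1.8322)²)^−0.8012

Each is multiplied by A; their sum is the LGN count. N_P falls
monotonically; N_M is unimodal, peaking at 1.8322°, reflecting the
parafoveal density peak of the magnocellular layers.

**RGC.** The literature tabulates RGC density (binocular, with the ~90%
RGC→LGN projection fraction already folded in) rather than a fitted form;
the package interpolates linearly between anchors at 2° (8,500 cells/deg²)
and 5° (3,000 cells/deg²).

**Expansion ratios.** Downstream over upstream counts: the high end of
each range divides the V1 upper bound by the LGN (or RGC) count, the low
end divides the loose lower bound. Ratios are formed from the *rounded*
counts and re-rounded to integers, matching how such ranges are quoted.

## The two reporting chains

The headline figures in this literature are "approximately" values:
5 mm² of surface, 3 mm³ of volume, 360,000 neurons. These only reproduce
if each intermediate is rounded to its reporting grain *before* feeding the
next stage (5 mm² × 0.6 mm = 3 mm³; 3 mm³ × 120,000 = 360,000), whereas
the full-precision chain gives 4.8499 × 0.6 × 120,000 ≈ 349,193. The
package therefore carries every quantity as a `(raw, paper_rounded)` pair
and prints both. The rounded chain is the reporting convention; the raw
chain is the honest estimate. Conflating them would either fail to
reproduce quoted figures or silently inflate the estimate by ~3%.

Reporting grains (configurable under `rounding:`): surface 1 mm², volume
1 mm³, V1 counts 10,000, LGN counts 1,000, RGC counts 500, ratios 1. The
grains are reverse-engineered from the quoted figures — they are a
reporting resolution, not a claim about uncertainty. Rounding is half-up
(148,500 → 150,000), not banker's; Python's built-in `round` would give
140,000 there.

## Parameters

All defaults ship in `src/vispop/data/defaults.yaml`; any subset can be
overridden from a user YAML file or CLI flags (flags > file > defaults).
Unknown keys are rejected rather than ignored.

| parameter | default | units | meaning |
|---|---|---|---|
| stimulus.area | 1.0 | deg² | stimulus area |
| stimulus.eccentricity | 3.0 | deg | stimulus **centre** (not nearest edge) |
| v1.laminar_depth | 0.75 | mm | thickness of layers 2/3/4B |
| v1.excitatory_fraction | 0.8 | – | excitatory share of V1 neurons |
| v1.density | 120,000 | neurons/mm³ | V1 volumetric density |
| v1.tuned_fraction | 0.75 | – | bandwidth < 30° share |
| v1.responsive_fraction | 0.55 | – | 1 − silent share |
| lgn.parvo / lgn.magno | as above | cells/deg² | magnification coefficients |
| rgc.anchors | (2°, 8500), (5°, 3000) | deg, cells/deg² | interpolation anchors |

Model coefficients are data, not code: substituting another species' fits
is a config edit.

## Numerical and design choices

- **Point vs integrated surface.** The default evaluates M at the stimulus
  centre and multiplies by area — the convention of the original
  calculation, exact in the limit of small stimuli. `integrated` mode
  treats the footprint as an eccentricity band of the stimulus height and
  computes w·∫M(|e|)de over [E−h/2, E+h/2] (adaptive quadrature,
  `scipy.integrate.quad`); |e| mirrors the radial map for stimuli
  straddling fixation. The modes agree within ~1% for a 1° patch at 3° and
  converge as the extent shrinks. This band geometry is an approximation:
  the true footprint of a square patch on cortex is not a pure
  eccentricity band.
- **Eccentricity domain.** Any E ≥ 0 is accepted; negative E is a domain
  error naming the value. Beyond 20° a warning is logged: the fits derive
  from parafoveal/peripheral data of unknown extent.
- **RGC extrapolation.** Refused outside [2°, 5°] by default — a two-point
  table gives no license to extrapolate. `extrapolate: true` extends the
  nearest segment linearly with a logged warning. When the RGC stage is
  refused, the other stages still report and the RGC fields/ratios are NaN
  with the reason recorded in `stage_errors`.
- **Degenerate stimuli.** Zero area yields zero counts and undefined
  (`None`) ratios; a stimulus small enough that a rounded stage count hits
  zero likewise reports no ratios rather than dividing by zero. Calling
  `expansion_ratios` directly on a zero stage count raises
  `UndefinedRatioError`.
- **Counts are real numbers.** Densities are continuous estimates; only
  paper-rounded fields sit on their grain.
- **Fraction ordering.** The tuned and responsive fractions enter
  multiplicatively, so the order in which the two corrections are applied
  is immaterial; the loose bound is defined from the upper bound as
  0.75 × 0.55 × N.
- **No randomness.** The method is closed-form, so sensitivity analysis is
  exhaustive grid evaluation (`sweep`) and one-at-a-time relative
  perturbation (`one_at_a_time`); there are no seeds anywhere.
- **LGN coefficient provenance.** It is not documented whether the LGN
  magnification fits fold in binocular viewing and the 90% RGC→LGN
  projection fraction the way the RGC table does; the coefficients are
  used as published. Anyone substituting their own LGN fits should check
  this convention.

## What the tests establish — and don't

The test suite checks exact closed-form values (frozen from an independent
log-domain evaluation, exp(log a − c·log(b+E)), agreeing to 1e−10
relative), shape properties (monotonicity of M and N_P, unimodality and
symmetry of N_M, exact anchor recovery), the bound ordering and
area-linearity invariants, the rounded-intermediate chain, and the CLI
contracts (atomic output, config round-trip, partial reports). Green tests
establish that the arithmetic and conventions are implemented faithfully —
not that the anatomical inputs are correct. The honest uncertainty in the
counts is dominated by the input parameters (densities, fractions, fit
coefficients), which is why every one of them is exposed and sweepable.

## Limitations

- Meridian-free: eccentricity is radial; horizontal/vertical anisotropy of
  magnification is not modelled.
- No foveal specialization (E < 0.5°) and no refitting to raw anatomy.
- No receptive-field overlap, tuning-curve, or information-theoretic
  modelling: the output is a population size, not a decoding analysis.
- Macaque defaults; other species require their own coefficient tables.
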