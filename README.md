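# vispop

Estimate how many neurons along the primate visual pathway — retinal
ganglion cells (RGC), lateral geniculate nucleus (LGN) relay cells, and
task-relevant primary visual cortex (V1) neurons — are engaged by a visual
stimulus of a given size and eccentricity.

These counts are rarely tabulated anywhere, yet they are what you need to
compare information content across stages of the pathway, to judge the
efficiency of cortical computation, or simply to know how large a neural
population an experiment actually probes. `vispop` computes them from
closed-form anatomical models with **every assumption exposed as a
parameter**, so the same calculation transfers to other stimuli, other
anatomical estimates, or other species.

## The model

For a stimulus of area $A$ (deg²) centred at eccentricity $E$ (deg):

- **V1 surface.** The areal cortical magnification factor
  $M(E) = 103\,(0.82 + E)^{-2.28}$ mm²/deg² gives the activated surface
  $S = A \cdot M(E)$.
- **V1 upper bound.** Only pyramidal neurons in layers 2/3/4B project to
  higher cortex: depth 0.75 mm, of which 80% of neurons are excitatory,
  giving an effective depth of $0.8 \times 0.75 = 0.6$ mm. With a
  volumetric density of 120,000 neurons/mm³, the upper bound is
  $N_{V1} = S \cdot 0.6 \cdot 120{,}000$.
- **V1 lower bounds.** Restricting to orientation-tuned neurons
  (orientation bandwidth < 30°, a fraction 0.75 across those layers) gives
  the tuned lower bound; further discounting neurons silent throughout
  recordings (responsive fraction 0.55) gives the loose lower bound
  $0.75 \times 0.55 \times N_{V1}$.
- **LGN.** Cell magnification factors
  $N_P(E) = 1{,}011{,}688\,(2.9144+E)^{-2.6798}$ (parvocellular) and
  $N_M(E) = 2{,}620.2\,(5.5638 + (E-1.8322)^2)^{-0.8012}$ (magnocellular),
  in cells/deg², each multiplied by $A$ and summed.
- **RGC.** Linear interpolation between tabulated densities of
  8,500 cells/deg² at 2° and 3,000 cells/deg² at 5° (binocular counts with
  the ~90% RGC→LGN projection fraction already folded in), times $A$.
- **Expansion ratios.** V1 count over upstream count, with the loose lower
  bound and the upper bound providing the ends of each range.

Every count is reported twice: the **raw** full-precision chain and a
**rounded-intermediate** chain that propagates values rounded at each
stage's reporting grain (1 mm², 1 mm³, 10,000 / 1,000 / 500 neurons) —
the convention behind the familiar headline figures. See
`docs/methods.md` for the reasoning and the grains.

## Worked example

The defaults are a 1×1 deg² stimulus at 3° eccentricity with macaque
constants. Running

```sh
vispop estimate
```

prints:

```
stage                                  raw         rounded  units
-----------------------------------------------------------------
Cortical surface                    4.8499               5  mm^2
Effective depth                        0.6             0.6  mm
Effective volume                   2.90994               3  mm^3
V1 upper bound                     349,193         360,000  neurons
V1 tuned lower bound               261,895         270,000  neurons
V1 loose lower bound               144,042         150,000  neurons
LGN parvocellular                 8,639.34           9,000  cells
LGN magnocellular                  555.727           1,000  cells
LGN total                         9,195.06           9,000  cells
RGC                               6,666.67           6,500  cells

Expansion ratios (rounded counts):
  LGN:V1 low (loose lower bound)          17 : 1
  LGN:V1 high (upper bound)               40 : 1
  RGC:V1 low (loose lower bound)          23 : 1
  RGC:V1 high (upper bound)               55 : 1
```

Reading: the stimulus activates ~5 mm² of V1; between ~150,000 (tuned and
responsive neurons only) and ~360,000 (every neuron in the volume) V1
neurons could inform an orientation judgement, fed by ~9,000 LGN cells and
~6,500 RGCs — a 17–40× (LGN) and 23–55× (RGC) expansion into cortex. The
raw column shows the same chain without intermediate rounding.

Library use mirrors the CLI:

```python
from vispop import StimulusSpec, default_models, estimate_pathway

est, ratios = estimate_pathway(StimulusSpec(area=1.0, eccentricity=3.0), default_models())
est.v1_upper.paper_rounded   # 360000.0
ratios.rgc_v1_high           # 55.0
```

Parameter sweeps (`vispop sweep --parameter stimulus.eccentricity
--range 2:5:0.5 --out sweep.csv`, or `vispop.sweep` /
`vispop.one_at_a_time` in Python) evaluate the chain over grids or
one-at-a-time perturbations, holding everything else fixed. All defaults
live in a YAML constants table and can be overridden per key from a config
file or the command line.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the default estimate from scratch and writes the headline
quantities (activated cortical surface in mm²; total LGN count) as JSON.
The model is closed-form and deterministic; the seed flag exists only for
interface uniformity.
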