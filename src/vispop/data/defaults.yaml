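# Default macaque anatomical constants for the visual-pathway calculator.
# Every value here is a model assumption, not code: override any subset in a
# user config file or from the command line.

stimulus:
  area: 1.0            # deg^2
  eccentricity: 3.0    # deg, stimulus centre
  extent: null         # optional [width, height] in deg for integrated mode
  mode: point          # point | integrated

v1:
  magnification:       # areal magnification M(E) = scale*(offset+E)^-exponent, mm^2/deg^2
    scale: 103.0
    offset: 0.82
    exponent: 2.28
  laminar_depth: 0.75        # mm, thickness of layers 2/3/4B (projection layers)
  excitatory_fraction: 0.8   # fraction of V1 neurons that are excitatory
  density: 120000.0          # neurons/mm^3 in V1
  tuned_fraction: 0.75       # fraction with orientation bandwidth < 30 deg
  responsive_fraction: 0.55  # fraction visually responsive (1 - silent fraction)

lgn:
  parvo:               # N_P(E) = scale*(offset+E)^-exponent, cells/deg^2
    scale: 1011688.0
    offset: 2.9144
    exponent: 2.6798
  magno:               # N_M(E) = scale*(floor+(E-center)^2)^-exponent, cells/deg^2
    scale: 2620.2
    floor: 5.5638
    center: 1.8322
    exponent: 0.8012

rgc:
  anchors:             # [eccentricity deg, density cells/deg^2]; binocular,
                       # 90% RGC->LGN projection fraction already folded in
    - [2.0, 8500.0]
    - [5.0, 3000.0]
  extrapolate: false   # refuse eccentricities outside the anchor range

rounding:              # reporting grains for the rounded-intermediate chain
  surface: 1.0         # mm^2
  volume: 1.0          # mm^3
  v1: 10000.0          # neurons
  lgn: 1000.0          # neurons
  rgc: 500.0           # cells
  ratio: 1.0           # dimensionless
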