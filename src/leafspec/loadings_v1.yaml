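# Versioned chemistry->spectrum loading calibration for the simulator.
# Each trait maps to a sum of Gaussian band responses (center nm, width nm,
# amplitude in reflectance units per trait unit) applied as
#   reflectance += amp * exp(-(lambda-center)^2 / (2 width^2)) * (trait - reference)
# Water content deepens the NIR/SWIR water-absorption troughs (970/1240/1450 nm,
# strongest at 1450); nitrogen deepens visible chlorophyll absorption and the
# red-edge shoulder. Na and B carry no spectral response at all: they emulate
# traits the spectrum cannot see.
version: 1
traits:
  wc:
    reference: 80.0
    gaussians:
      - {center: 970.0, width: 30.0, amplitude: -0.0010}
      - {center: 1240.0, width: 40.0, amplitude: -0.0018}
      - {center: 1450.0, width: 60.0, amplitude: -0.0035}
  n:
    reference: 3.2
    gaussians:
      - {center: 640.0, width: 45.0, amplitude: -0.012}
      - {center: 700.0, width: 20.0, amplitude: -0.008}
  p:
    reference: 0.32
    gaussians:
      - {center: 1100.0, width: 40.0, amplitude: 0.15}
  k:
    reference: 2.0
    gaussians:
      - {center: 1550.0, width: 50.0, amplitude: -0.010}
  mg:
    reference: 0.40
    gaussians:
      - {center: 900.0, width: 30.0, amplitude: 0.07}
  ca:
    reference: 0.95
    gaussians:
      - {center: 1350.0, width: 45.0, amplitude: -0.015}
  s:
    reference: 0.22
    gaussians:
      - {center: 1050.0, width: 35.0, amplitude: 0.12}
  na:
    reference: 0.0065
    gaussians: []
  fe:
    reference: 100.0
    gaussians:
      - {center: 600.0, width: 30.0, amplitude: -0.0002}
  mn:
    reference: 60.0
    gaussians:
      - {center: 820.0, width: 30.0, amplitude: 0.0005}
  b:
    reference: 40.0
    gaussians: []
  cu:
    reference: 9.0
    gaussians:
      - {center: 1640.0, width: 40.0, amplitude: 0.002}
  zn:
    reference: 37.0
    gaussians:
      - {center: 1150.0, width: 30.0, amplitude: 0.0008}
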