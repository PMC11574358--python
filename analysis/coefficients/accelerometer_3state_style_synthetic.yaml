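# SYNTHETIC STAND-IN coefficient set (not published values).
#
# Emulates the *shape* of a three-category accelerometer-only calibration
# (flight / resting at colony / resting on water) reported in kJ h^-1 for a
# 365 g bird, which tends to yield lower DEE estimates because flapping and
# gliding are pooled into one "flight" cost.  Placeholders only; converted
# to kJ g^-1 day^-1 (x 24 / 365).
name: accelerometer_3state_style_synthetic
provenance: >-
  synthetic placeholder emulating an accelerometer-only three-state
  calibration; one pooled flight cost applied to flapping and gliding
coefficients:
  flight: 2.63        # 40 kJ/h at 365 g
  rest_colony: 0.99   # 15 kJ/h at 365 g
  rest_water: 1.58    # 24 kJ/h at 365 g
mapping:
  flapping: flight
  gliding: flight
  colony: rest_colony
  rest_land: rest_colony
  swimming: rest_water
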