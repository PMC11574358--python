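# SYNTHETIC STAND-IN coefficient set (not published values).
#
# Emulates the *shape* of an older kittiwake calibration built from
# fine-scale behavioural observations and radio telemetry, whose activity
# costs were reported in ml CO2 g^-1 h^-1 and which tends to yield higher
# DEE estimates than the present calibration.  The numbers below are
# placeholders chosen for that qualitative behaviour; edit this file to use
# a real coefficient set.  Values already converted to kJ g^-1 day^-1
# (1 ml CO2/g/h = 0.66312 kJ/g/day at 27.63 J/ml).
name: radio_telemetry_style_synthetic
provenance: >-
  synthetic placeholder emulating an observation/telemetry-based calibration;
  flight categories averaged into flapping, nest attendance and loafing
  averaged into resting/gliding
coefficients:
  flapping: 4.38      # mean of "commuting" and "searching" flight stand-ins
  swimming: 2.19
  rest_colony_glide: 1.33   # mean of "nest attendance" and "loafing" stand-ins
mapping:
  colony: rest_colony_glide
  gliding: rest_colony_glide
  rest_land: rest_colony_glide
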