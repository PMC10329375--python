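name: control2
description: >
  Passive patient model without airway closure but with a bilinear
  compliance: lower inflection point 10 cmH2O, 20 mL/cmH2O below and
  40 mL/cmH2O above it; airway resistance 10 cmH2O/L/s.
system:
  rrs: 10.0
  compliance:
    bilinear:
      c_below: 20.0
      c_above: 40.0
      lip: 10.0
circuit:
  ccirc: 2.0
  rcirc: 0.0
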