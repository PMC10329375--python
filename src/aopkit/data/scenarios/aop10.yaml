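name: aop10
description: >
  Passive patient model with airway closure: opening pressure 10 cmH2O,
  airway resistance 10 cmH2O/L/s, linear compliance 40 mL/cmH2O.
system:
  rrs: 10.0
  compliance:
    linear:
      crs: 40.0
  aop: 10.0
circuit:
  ccirc: 2.0
  rcirc: 0.0
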