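# Default gEUD model parameters per structure.
# a: volume-effect exponent; alpha_beta: LQ alpha/beta ratio in Gy.
# Trachea and bronchus are deliberately absent: no validated parameter set
# exists for them and the engine refuses to guess.
reference_fraction_dose: 2.0
structures:
  ptv: {a: 10.0, alpha_beta: 10.0}
  lung: {a: 1.0, alpha_beta: 4.0}
  heart: {a: 3.0, alpha_beta: 3.7}
  spinal_cord: {a: 20.0, alpha_beta: 3.0}
  esophagus: {a: 16.67, alpha_beta: 4.9}
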