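# Known-drug Gaussian parameters for the KDI desirability indexes.
# Each descriptor's (mean, sigma) comes from fitting a Gaussian to the
# descriptor distribution of drugs in clinical use (Eurtivong & Reynisson,
# Mol. Inform. 2019).  Units: MW g/mol; PSA Å²; others dimensionless counts
# or logP.
descriptors:
  MW:   {mean: 371.76, sigma: 112.76}
  logP: {mean: 2.82,   sigma: 2.21}
  HD:   {mean: 1.88,   sigma: 1.7}
  HA:   {mean: 5.72,   sigma: 2.86}
  RB:   {mean: 4.44,   sigma: 3.55}
  PSA:  {mean: 79.4,   sigma: 54.16}
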