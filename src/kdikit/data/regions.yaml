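# Default chemical-space regions, ordered innermost (most restrictive) to
# outermost.  These are the conventional lead-like / drug-like / Known Drug
# Space bounds of the virtual-screening literature (lead-like and KDS after
# Zhu et al., J. Med. Chem. 2012 and the Reynisson-group KDS papers;
# drug-like after Lipinski's rule of five plus Veber's criteria).  They are
# package defaults, not a re-derivation: pass your own file to use other
# bounds.  Intervals are closed; ".inf" / "-.inf" are allowed.
nested: true
regions:
  - name: lead-like
    bounds:
      MW:   [0, 300]
      logP: [-.inf, 3]
      HD:   [0, 3]
      HA:   [0, 3]
      PSA:  [0, 60]
      RB:   [0, 3]
  - name: drug-like
    bounds:
      MW:   [0, 500]
      logP: [-.inf, 5]
      HD:   [0, 5]
      HA:   [0, 10]
      PSA:  [0, 140]
      RB:   [0, 10]
  - name: known-drug-space
    bounds:
      MW:   [0, 800]
      logP: [-.inf, 6.5]
      HD:   [0, 7]
      HA:   [0, 15]
      PSA:  [0, 180]
      RB:   [0, 17]
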