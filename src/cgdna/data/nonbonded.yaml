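# Nonbonded constants: excluded volume, Watson-Crick pairing, base stacking,
# coaxial stacking.  Units: A, kcal/mol.
#
# base_pair.d0 is the N-N distance of a WC pair in the ideal-duplex
# generator; base_stack.d0 is its adjacent-pair midpoint distance.  Pairing
# depths give G-C (three hydrogen bonds) a deeper well than A-T (two).
# Stacking depths are dimer-step specific (5'->3' key on the leading
# strand), ordered per nearest-neighbor dimer thermodynamics with the mean
# stacking-entropy penalty already folded into the depth.  The overall
# depth scale is calibrated so that short stem-loop motifs melt inside the
# 25-110 C replica ladder (see docs/methods.md).
cutoff: 18.0
excluded_volume:
  epsilon: 1.0
base_pair:
  d0: 8.9095
  sigma: 2.0
  orient_lo: 0.35
  orient_hi: 0.80
  depth:
    AT: 2.40
    GC: 3.60
base_stack:
  d0: 4.3594
  sigma: 1.2
  depth:
    AA: 1.60
    AC: 2.30
    AG: 2.05
    AT: 1.41
    CA: 2.32
    CC: 2.94
    CG: 3.47
    CT: 2.05
    GA: 2.08
    GC: 3.58
    GG: 2.94
    GT: 2.30
    TA: 0.93
    TC: 2.08
    TG: 2.32
    TT: 1.60
coaxial_stack:
  depth: 1.60
  d0: 4.3594
  sigma: 1.5
  align_lo: 0.40
  align_hi: 0.90
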