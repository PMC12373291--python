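# Loop (single-stranded / unpaired) bonded parameter set.
# Soft force constants model flexible ssDNA; equilibria match the
# deterministic loop reference chain so the set has an exactly realizable
# zero-energy geometry.  Units: A, degrees, kcal/mol.
bonds:
  PC: {r0: 3.7, k: 10.0}
  CN: {r0: 3.3, k: 10.0}
  CP: {r0: 4.0, k: 10.0}
angles:
  PCN: {theta0: 108.0, k: 3.0}
  NCP: {theta0: 100.71, k: 1.5}
  PCP: {theta0: 112.0, k: 3.0}
  CPC: {theta0: 105.0, k: 3.0}
dihedrals:
  PCPC: {phi0: 150.0, k: 0.3}
  CPCN: {phi0: -60.0, k: 0.3}
  CPCP: {phi0: -170.0, k: 0.3}
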