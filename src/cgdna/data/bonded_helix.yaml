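# Helix (base-paired) bonded parameter set.
# Equilibria are the internal coordinates of the ideal B-form CG duplex
# generator; stiff constants hold paired regions at canonical geometry
# during final refinement.  Units: A, degrees, kcal/mol.
bonds:
  PC: {r0: 3.6455, k: 50.0}
  CN: {r0: 3.3242, k: 50.0}
  CP: {r0: 3.9824, k: 50.0}
angles:
  PCN: {theta0: 150.004, k: 25.0}
  NCP: {theta0: 77.233, k: 25.0}
  PCP: {theta0: 115.568, k: 25.0}
  CPC: {theta0: 99.760, k: 25.0}
dihedrals:
  PCPC: {phi0: 145.865, k: 8.0}
  CPCN: {phi0: -59.452, k: 8.0}
  CPCP: {phi0: -169.254, k: 8.0}
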