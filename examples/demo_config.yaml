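# End-to-end demo configuration: simulate a perfused WT cohort, a PRM
# fixture and a pendrin-KO cohort, derive phenotypes, quantify, and
# integrate proteome with phenotype.
seed: 7
simulate:
  n_tubules: 12
  ko_n_wt: 5
  ko_n_ko: 5
  ko_n_proteins: 600   # reduced untargeted depth keeps the demo quick
  ko_effect: -1.5
targeted:
  ppm_max: 10.0
  coelution_tol: 0.2
untargeted:
  shift: 1.8
  width: 0.3
  fc_cut: 1.0
  p_cut: 0.05
integrate:
  anchor: SLC26A4
  use_abs_dvte: true
  n_permutations: 1000
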