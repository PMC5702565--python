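# Printed reference values from the PPROM candidate-gene study this package
# re-implements, used by the reproduction layer. Allele frequencies in the
# companion table are over the combined discovery + follow-up cohorts.
cohort:
  wes_cases: 76
  wes_controls: 43
  followup_cases: 188
  followup_controls: 175
  combined_cases: 264
  combined_controls: 218
# Heterozygous carrier counts among the combined 264 cases, as stated in the
# study narrative for the case-only mutations.
case_carrier_counts:
  rs150487186: 2   # CARD6 nonsense
  rs5743490: 6     # DEFB1 nonsense
  rs74754826: 6    # MBL2 nonsense
  rs765522475: 1   # NLRP10 nonsense
  rs143482452: 1   # FUT2 nonsense (rare)
fut2_homozygotes:
  variant_id: rs601338
  case_hom: 16
  case_n: 76
  control_hom: 4
  control_n: 43
  reported_case_pct: 21      # integer percent as printed
  reported_control_pct: 9.3  # one decimal as printed
detection:
  allele_freq: 0.005
  n_chromosomes: 304   # reconciles the printed 78%; 152 chromosomes gives 53%
  reported_percent: 78
burden:
  reported_empirical_p: 0.0416
  n_perm: 10000
  reported_case_higher: 10
ancestry:
  n_markers: 102
  delta: 0.733
  case_theta_mean: 0.695
  case_theta_sd: 0.073
  control_theta_mean: 0.698
  control_theta_sd: 0.087
case_only_genes: [CARD6, DEFB1, FUT2, MBL2, NLRP10, NOD2]
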