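# Demonstration scenario: a single steep contact zone at the scale of the
# study system — chloroplast cline centered at 0.43 with width 0.05, 234
# nuclear-chloroplast candidate genes of which 12 are planted on the
# chloroplast cline (co-introgressing). For demonstration only; the test
# suite uses smaller, faster scenarios.
seed: 1
output_dir: steep_zone_out
simulate:
  n_samples: 300
  n_genes: 234
  co_fraction: 0.0513   # 12 of 234
  cp_center: 0.43
  cp_width: 0.05
  nuc_center: 0.68
  nuc_width: 0.3
scan:
  n_starts: 8
quantgen:
  trait_name: PhiPSII
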