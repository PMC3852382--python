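# End-to-end demonstration: simulate an intermated biparental population with
# one QTL per signaling gate, scan for marker x environment interactions,
# smooth + FDR, call intervals and classify gate patterns.
# Run:  stressgate run --config examples/demo.yaml
seed: 7
outdir: stressgate_demo
simulate:
  design: ibm
  n_lines: 150
  n_chromosomes: 6
  markers_per_chromosome: 15
  chrom_length: 140.0
  intermating_generations: 4
  blocks: 4
  r2: 0.3
smooth:
  window: 3
  method: simes
  fdr_alpha: 0.05
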