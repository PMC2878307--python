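# Demo pipeline: simulate a 2-Mb genome with planted Alu-like elements,
# then run every analysis stage. Completes in well under a minute on one CPU.
#   alunuc run-all --config examples/demo.yaml
seed: 1
outdir: alunuc_demo
simulate:
  genome_len: 2000000
spectrum:
  step: AA/TT
  n_frag: 200
  frag_len: 8193
  modes: [raw, masked, random]
profile:
  classes: [dimer, FLAM, FRAM]
  anchor: center
  flank: 1000
  window_w: 21
tiling:
  max_dist: 600
  bin_width: 25
  shuffles: 10
expression:
  replicates: 10
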