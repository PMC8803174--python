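# Desk-scale profile: one core, minutes per stage.  Usage:
#   grnevo --config examples/config_desk.yaml wl --out weights.csv
#   grnevo --config examples/config_desk.yaml sample --weights weights.csv --out archive.txt
#   grnevo --config examples/config_desk.yaml evolve --out-dir lineages/
wl:
  n_nodes: 32
  n_edges: 80
  beta: 2.0
  mu: 0.0
  bins: 100
  max_mcs: 25000
  flatness: 0.8
  seed: 0
sample:
  n_mcs: 20000
  sample_every: 20
  burn_in: 1000
  runs: 1
  seed: 1
evolve:
  mode: evo50
  population: 1000
  replicates: 16
  generations: -1   # protocol default: 150 for evo50, 200 for evo90
  seed: 2
analyze:
  criterion: strict
  threshold: 0.8
  bins: 100
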