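# Published-campaign profile (cluster scale: the sampler stage alone is
# ~1e8 Monte Carlo steps in total, and the evolutionary campaign is 1e5
# replicates; budget days of CPU, or split runs across nodes by seed).
wl:
  n_nodes: 32
  n_edges: 80
  beta: 2.0
  mu: 0.0
  bins: 100
  max_mcs: 2000000
  flatness: 0.8
  seed: 0
sample:
  n_mcs: 10000000
  sample_every: 20
  burn_in: 1000
  runs: 10          # ten independent chains -> ~50,000 samples per bin
  seed: 1
evolve:
  mode: evo50
  population: 1000
  replicates: 100000
  generations: -1
  seed: 2
analyze:
  criterion: strict
  threshold: 0.8
  bins: 100
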