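# Synthetic end-to-end demo: scale-free network, two planted contrasts,
# random gene sets.  Runs in well under a minute.
output_dir: netprio_demo_out
synthetic:
  seed: 11
  network:
    n_nodes: 1500
    edges_per_new_node: 2
  expression:
    n_up: 50
    n_down: 50
    fc_low: 1.8
    fc_high: 3.0
    noise_sd: 0.3
  gene_sets:
    n_sets: 40
    size_low: 10
    size_high: 80
deg:
  threshold: 1.5
rwr:
  seed_gene: auto
  restart: 0.7
  tolerance: 1.0e-10
  max_iterations: 10000
enrichment:
  alpha: 0.05
  overlap_cutoff: 0.6
  method: fisher
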