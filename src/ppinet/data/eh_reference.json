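{
  "description": "Published reference values from the essential-hypertension PPI study whose protocol this package implements. These are inputs for protocol-arithmetic checks, not recomputable quantities: the giant network derives from a historical STRING v9.0 snapshot.",
  "giant_nodes": 535,
  "giant_edges": 2572,
  "giant_diameter": 12,
  "giant_mspl": 5.23,
  "backbone_nodes": 27,
  "backbone_edges": 39,
  "n_seed_genes": 69,
  "central_gene": "NOS3",
  "central_gene_bc": 0.27867,
  "largest_degree": 43,
  "largest_degree_gene": "KNG1",
  "high_bc_fraction": 0.05,
  "k_max": 7,
  "draws_per_k": 30,
  "seed_subnetwork_composition": {
    "connector": 6,
    "seed_only": 60,
    "backbone_only": 20,
    "seed_and_backbone": 7
  }
}
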