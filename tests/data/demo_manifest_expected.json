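{
 "stages": {
  "coexnet": {
   "n_edges_root": 2450,
   "n_edges_shoot": 4950,
   "n_nodes_root": 100,
   "n_nodes_shoot": 100,
   "status": "ok"
  },
  "diffexpr": {
   "n_degs_root_RWC10": 40,
   "n_degs_root_RWC40": 97,
   "n_degs_root_RWC60": 44,
   "n_degs_root_RWC80": 0,
   "n_degs_root_rehydrated": 0,
   "n_degs_shoot_RWC10": 100,
   "n_degs_shoot_RWC40": 99,
   "n_degs_shoot_RWC60": 98,
   "n_degs_shoot_RWC80": 98,
   "n_degs_shoot_rehydrated": 0,
   "status": "ok"
  },
  "inputs": {
   "n_genes": 1200,
   "n_samples": 36,
   "status": "ok"
  },
  "metabolomics": {
   "n_fold_change_rows": 300,
   "n_significant_up": 29,
   "status": "ok"
  },
  "physiology": {
   "n_viability_treatments": 5,
   "n_weight_records": 15,
   "status": "ok",
   "survival_threshold_band": "70-60"
  },
  "phytohormones": {
   "n_hormones": 3,
   "status": "ok"
  }
 }
}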