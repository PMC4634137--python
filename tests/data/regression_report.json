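{
  "chip_intersection": {
    "bound_by_both": 31,
    "bound_by_either": 61,
    "chip_ab_overlap": 102,
    "n_candidates": 67,
    "n_chip_a": 238,
    "n_chip_b": 245,
    "p_both": 1.920568182e-36,
    "p_chip_ab": 4.513130218e-77,
    "p_either": 3.803209402e-63
  },
  "cluster_sizes": [
    120,
    345,
    208,
    99,
    159,
    147,
    104,
    155,
    76,
    144,
    95,
    107
  ],
  "cross_species": {
    "K": 874,
    "N": 5000,
    "enrichment_factor": 2.817719184,
    "k": 33,
    "n": 67,
    "n_missing": 0,
    "p": 1.933159872e-09
  },
  "dendrogram_celltype_purity": 1.0,
  "kmer_min_p_bonferroni": 1.045636664e-25,
  "marker_validation": {
    "fraction_passing": 1.0,
    "mean_fold_cochlea": 12.38925157,
    "mean_fold_vestibule": 12.31082192,
    "n_excluded": 50,
    "n_validated": 100
  },
  "motif_enrichment_full": {
    "K": 922,
    "N": 5000,
    "enrichment_factor": 2.844227356,
    "k": 75,
    "n": 143,
    "n_missing": 0,
    "p": 1.26557823e-20
  },
  "motif_enrichment_narrowed": {
    "K": 294,
    "N": 5000,
    "enrichment_factor": 7.968222254,
    "k": 67,
    "n": 143,
    "n_missing": 0,
    "p": 2.525944482e-46
  },
  "n_de_selected": 1759,
  "n_features_detected": 3524,
  "n_features_input": 5000,
  "n_hc_enriched": 143,
  "n_markers": {
    "ENHC": 50,
    "HC": 50,
    "NEC": 50
  },
  "n_putative_targets": 67,
  "positional_mode_bin": [
    -75,
    -50
  ],
  "seed": 1,
  "shift_test": {
    "median_difference": 0.6286362853,
    "method": "asymptotic",
    "n_rest": 3315,
    "n_set": 209,
    "p": 6.460187945e-50,
    "p_two_sided": 1.292037589e-49,
    "rank_sum": 579621.0,
    "set_label": "chip_targets"
  },
  "top_kmer": "ATGGCAAC"
}
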