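dataset	quantity	numerator	denominator	printed_percent
1541_loci	bayesian_nodes_pp_over_0.95	27	31	87
1541_loci	ml_nodes_bootstrap_over_75	20	31	65
416_loci	bayesian_nodes_pp_over_0.95	24	28	86
416_loci	ml_nodes_bootstrap_over_75	14	28	50
416_loci	nodes_disagreeing_bayes_vs_ml	12	28	43
416_loci	species_tree_nodes_over_50	11	28	39
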