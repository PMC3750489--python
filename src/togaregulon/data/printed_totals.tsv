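quantity	printed_value	expected_agreement
n_regulators	19	AGREE
n_transporter_genes	86	AGREE
n_enzymes	127	EXPECTED-MISMATCH
n_total_genes	241	EXPECTED-MISMATCH
n_regulon_genes	181	AGREE
n_tf_binding_sites	40	AGREE
n_target_genes	163	AGREE
n_regulon_models	19	AGREE
n_tfs_tmaritima	18	AGREE
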