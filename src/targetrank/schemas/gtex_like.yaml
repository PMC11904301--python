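# Normal-tissue expression snapshot: one row per gene, one numeric
# column per tissue (linear-scale expression, e.g. median TPM).
key_column: gene
kind: gene_table
required_columns: []
min_numeric_columns: 1
units: linear expression per tissue
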