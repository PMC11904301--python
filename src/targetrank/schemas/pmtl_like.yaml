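# Relevant molecular target list membership: binary flag per gene.
key_column: gene
kind: gene_table
required_columns: [pmtl]
min_numeric_columns: 1
units: 0/1 flag
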