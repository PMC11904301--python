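# Surface-localization evidence: integrated 0-5 confidence score per gene.
key_column: gene
kind: gene_table
required_columns: [evidence_score]
min_numeric_columns: 1
units: evidence score 0-5
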