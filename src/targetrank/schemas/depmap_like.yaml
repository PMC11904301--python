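# Dependency snapshot: one numeric column per cell line, named
# "<phenotype>.<line>"; higher values mean stronger dependency of the
# line on the gene.
key_column: gene
kind: gene_table
required_columns: []
min_numeric_columns: 1
units: dependency effect per cell line
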