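# Therapeutic reagent records: one row per (gene, phenotype, modality,
# status) record; genes repeat. Categorical columns are preserved for
# label derivation.
key_column: gene
kind: record_table
required_columns: [phenotype, modality, status]
min_numeric_columns: 0
units: categorical records
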