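format-version: 1.2
ontology: doid-mini
remark: miniature synthetic subset of the Human Disease Ontology (DOID) for testing

[Term]
id: DOID:4
name: disease

[Term]
id: DOID:0050117
name: disease by infectious agent
is_a: DOID:4 ! disease

[Term]
id: DOID:934
name: viral infectious disease
is_a: DOID:0050117 ! disease by infectious agent

[Term]
id: DOID:2945
name: severe acute respiratory syndrome
is_a: DOID:934 ! viral infectious disease

[Term]
id: DOID:0080600
name: COVID-19
is_a: DOID:934 ! viral infectious disease
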