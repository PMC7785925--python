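format-version: 1.2
ontology: uberon-mini
remark: miniature synthetic subset of UBERON (anatomy) for testing; not the full vocabulary

[Term]
id: UBERON:0000062
name: organ

[Term]
id: UBERON:0000160
name: intestine
is_a: UBERON:0000062 ! organ

[Term]
id: UBERON:0000059
name: large intestine
is_a: UBERON:0000160 ! intestine

[Term]
id: UBERON:0001052
name: rectum
is_a: UBERON:0000059 ! large intestine

[Term]
id: UBERON:0002108
name: small intestine
is_a: UBERON:0000160 ! intestine

[Term]
id: UBERON:0002116
name: ileum
is_a: UBERON:0002108 ! small intestine

[Term]
id: UBERON:0000995
name: uterus
is_a: UBERON:0000062 ! organ

[Term]
id: UBERON:0002450
name: decidua
relationship: part_of UBERON:0000995 ! uterus

[Term]
id: UBERON:0002048
name: lung
is_a: UBERON:0000062 ! organ

[Term]
id: UBERON:0002107
name: liver
is_a: UBERON:0000062 ! organ

[Term]
id: UBERON:0000948
name: heart
is_a: UBERON:0000062 ! organ

[Term]
id: UBERON:0002110
name: gall bladder
is_a: UBERON:0000062 ! organ

[Term]
id: UBERON:0002113
name: kidney
is_a: UBERON:0000062 ! organ

[Term]
id: UBERON:0000178
name: blood
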