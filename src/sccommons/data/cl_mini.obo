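format-version: 1.2
ontology: cl-mini
remark: miniature synthetic subset of the Cell Ontology (CL) for testing; not the full vocabulary

[Term]
id: CL:0000000
name: cell

[Term]
id: CL:0000003
name: native cell
is_a: CL:0000000 ! cell

[Term]
id: CL:0000066
name: epithelial cell
is_a: CL:0000003 ! native cell

[Term]
id: CL:0000075
name: columnar/cuboidal epithelial cell
is_a: CL:0000066 ! epithelial cell

[Term]
id: CL:0000212
name: absorptive cell
is_a: CL:0000075 ! columnar/cuboidal epithelial cell

[Term]
id: CL:0000584
name: enterocyte
is_a: CL:0000212 ! absorptive cell

[Term]
id: CL:1000334
name: enterocyte of epithelium of small intestine
is_a: CL:0000584 ! enterocyte

[Term]
id: CL:1000335
name: immature enterocyte
is_a: CL:0000584 ! enterocyte

[Term]
id: CL:4030026
name: BEST4+ enterocyte
is_a: CL:0000584 ! enterocyte

[Term]
id: CL:0000160
name: goblet cell
is_a: CL:0000075 ! columnar/cuboidal epithelial cell

[Term]
id: CL:0000064
name: ciliated cell
is_a: CL:0000066 ! epithelial cell

[Term]
id: CL:0002063
name: type II pneumocyte
is_a: CL:0000066 ! epithelial cell

[Term]
id: CL:0000235
name: macrophage
is_a: CL:0000003 ! native cell

[Term]
id: CL:0000576
name: monocyte
is_a: CL:0000003 ! native cell

[Term]
id: CL:0000115
name: endothelial cell
is_a: CL:0000066 ! epithelial cell

[Term]
id: CL:0009999
name: obsolete test cell
is_obsolete: true
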