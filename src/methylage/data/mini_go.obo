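format-version: 1.2
ontology: methylage-mini-bp
remark: Synthetic miniature Biological-Process-like ontology shipped so that enrichment and ancestor collapsing run without the full Gene Ontology. Levels below the root: 1 = broad domains, 2 = supra-category ancestors, 3 = leaf annotation terms.

[Term]
id: TOY:0000001
name: biological_process
namespace: biological_process

[Term]
id: TOY:0000002
name: developmental process
namespace: biological_process
is_a: TOY:0000001 ! biological_process

[Term]
id: TOY:0000003
name: metabolic process
namespace: biological_process
is_a: TOY:0000001 ! biological_process

[Term]
id: TOY:0000004
name: regulation of biological process
namespace: biological_process
is_a: TOY:0000001 ! biological_process

[Term]
id: TOY:0000005
name: localization
namespace: biological_process
is_a: TOY:0000001 ! biological_process

[Term]
id: TOY:0000010
name: system development
namespace: biological_process
is_a: TOY:0000002 ! developmental process

[Term]
id: TOY:0000011
name: anatomical structure development
namespace: biological_process
is_a: TOY:0000002 ! developmental process

[Term]
id: TOY:0000012
name: anatomical structure morphogenesis
namespace: biological_process
is_a: TOY:0000002 ! developmental process

[Term]
id: TOY:0000013
name: tissue development
namespace: biological_process
is_a: TOY:0000002 ! developmental process

[Term]
id: TOY:0000014
name: nitrogen compound metabolic process
namespace: biological_process
is_a: TOY:0000003 ! metabolic process

[Term]
id: TOY:0000015
name: regulation of cellular process
namespace: biological_process
is_a: TOY:0000004 ! regulation of biological process

[Term]
id: TOY:0000016
name: regulation of developmental process
namespace: biological_process
is_a: TOY:0000004 ! regulation of biological process

[Term]
id: TOY:0000017
name: transport
namespace: biological_process
is_a: TOY:0000005 ! localization

[Term]
id: TOY:0000100
name: muscle system development
namespace: biological_process
is_a: TOY:0000010 ! system development

[Term]
id: TOY:0000101
name: neural system development
namespace: biological_process
is_a: TOY:0000010 ! system development

[Term]
id: TOY:0000102
name: skeletal structure development
namespace: biological_process
is_a: TOY:0000011 ! anatomical structure development

[Term]
id: TOY:0000103
name: organ morphogenesis
namespace: biological_process
is_a: TOY:0000011 ! anatomical structure development
is_a: TOY:0000012 ! anatomical structure morphogenesis

[Term]
id: TOY:0000104
name: epithelium development
namespace: biological_process
is_a: TOY:0000013 ! tissue development

[Term]
id: TOY:0000105
name: amine metabolic process
namespace: biological_process
is_a: TOY:0000014 ! nitrogen compound metabolic process

[Term]
id: TOY:0000106
name: regulation of cell differentiation
namespace: biological_process
is_a: TOY:0000015 ! regulation of cellular process
is_a: TOY:0000016 ! regulation of developmental process

[Term]
id: TOY:0000107
name: ion transport
namespace: biological_process
is_a: TOY:0000017 ! transport

[Term]
id: TOY:0000108
name: protein catabolic process
namespace: biological_process
is_a: TOY:0000014 ! nitrogen compound metabolic process

[Term]
id: TOY:0000109
name: regulation of growth
namespace: biological_process
is_a: TOY:0000016 ! regulation of developmental process
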