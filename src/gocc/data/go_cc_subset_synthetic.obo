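format-version: 1.2
ontology: go
remark: Synthetic hand-built subset of the Gene Ontology Cellular Component
remark: domain for tests and demos. Term IDs and names are real GO entries;
remark: the hierarchy is simplified (some intermediate terms are omitted and
remark: children attach directly to their sub-hierarchy root).

[Term]
id: GO:0005575
name: cellular_component

[Term]
id: GO:0005576
name: extracellular region
is_a: GO:0005575 ! cellular_component

[Term]
id: GO:0005623
name: cell
is_a: GO:0005575 ! cellular_component

[Term]
id: GO:0009295
name: nucleoid
is_a: GO:0005575 ! cellular_component

[Term]
id: GO:0016020
name: membrane
is_a: GO:0005575 ! cellular_component

[Term]
id: GO:0019012
name: virion
is_a: GO:0005575 ! cellular_component

[Term]
id: GO:0030054
name: cell junction
is_a: GO:0005575 ! cellular_component

[Term]
id: GO:0031012
name: extracellular matrix
is_a: GO:0005575 ! cellular_component

[Term]
id: GO:0031974
name: membrane-enclosed lumen
is_a: GO:0005575 ! cellular_component

[Term]
id: GO:0039679
name: viral occlusion body
is_a: GO:0005575 ! cellular_component

[Term]
id: GO:0043226
name: organelle
is_a: GO:0005575 ! cellular_component

[Term]
id: GO:0044420
name: extracellular matrix component
is_a: GO:0005575 ! cellular_component

[Term]
id: GO:0044421
name: extracellular region part
is_a: GO:0005575 ! cellular_component

[Term]
id: GO:0044422
name: organelle part
is_a: GO:0005575 ! cellular_component

[Term]
id: GO:0044423
name: virion part
is_a: GO:0005575 ! cellular_component

[Term]
id: GO:0044425
name: membrane part
is_a: GO:0005575 ! cellular_component

[Term]
id: GO:0044456
name: synapse part
is_a: GO:0005575 ! cellular_component

[Term]
id: GO:0044464
name: cell part
is_a: GO:0005575 ! cellular_component

[Term]
id: GO:0045202
name: synapse
is_a: GO:0005575 ! cellular_component

[Term]
id: GO:0055044
name: symplast
is_a: GO:0005575 ! cellular_component

[Term]
id: GO:0005737
name: cytoplasm
is_a: GO:0044464 ! cell part

[Term]
id: GO:0005829
name: cytosol
relationship: part_of GO:0005737 ! cytoplasm

[Term]
id: GO:0005634
name: nucleus
synonym: "cell nucleus" EXACT []
is_a: GO:0043226 ! organelle

[Term]
id: GO:0005886
name: plasma membrane
synonym: "cell membrane" EXACT []
is_a: GO:0016020 ! membrane

[Term]
id: GO:0005783
name: endoplasmic reticulum
synonym: "ER" EXACT []
is_a: GO:0043226 ! organelle

[Term]
id: GO:0005739
name: mitochondrion
synonym: "mitochondria" EXACT []
is_a: GO:0043226 ! organelle

[Term]
id: GO:0005794
name: Golgi apparatus
is_a: GO:0043226 ! organelle

[Term]
id: GO:0030496
name: midbody
is_a: GO:0044464 ! cell part

[Term]
id: GO:0043234
name: protein complex
is_a: GO:0005575 ! cellular_component

[Term]
id: GO:0005852
name: eukaryotic translation initiation factor 3 complex
is_a: GO:0043234 ! protein complex

[Term]
id: GO:0000502
name: proteasome complex
is_a: GO:0043234 ! protein complex

[Term]
id: GO:0008150
name: biological_process
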