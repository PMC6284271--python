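"""Score predicted triplets against a gold standard.

Builds a tiny BioC XML gold collection in memory, reads it back through
the gold-standard reader, and scores a prediction set that gets two of
three triplets right plus one spurious one.
"""

from gocc.evaluation import read_gold, score

GOLD_XML = """<?xml version="1.0"?>
<collection><source>demo</source><document><id>12345</id><passage><offset>0</offset>
 <annotation id="1"><infon key="gene_id">g1</infon><infon key="go_id">GO:0005737</infon></annotation>
 <annotation id="2"><infon key="gene_id">g2</infon><infon key="go_id">GO:0043234</infon></annotation>
 <annotation id="3"><infon key="gene_id">g3</infon><infon key="go_id">GO:0005634</infon></annotation>
</passage></document></collection>
"""

gold = read_gold(GOLD_XML)
predicted = {
    ("12345", "g1", "GO:0005737"),
    ("12345", "g2", "GO:0043234"),
    ("12345", "g9", "GO:0016020"),
}
r = score(predicted, gold)
print(f"TP={r.tp} FP={r.fp} FN={r.fn}")
print(f"precision={r.precision:.3f} recall={r.recall:.3f} F1={r.f1:.3f}")

# Triplets are compared exactly: two matches out of three predictions gives
# precision 0.667; two of three gold triplets recovered gives recall 0.667.
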