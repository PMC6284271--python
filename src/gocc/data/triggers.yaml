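# Default trigger lexicon: trigger class -> lemma/surface list.
# Lists are deliberately configuration, not code; matching is against the
# token lemma or lowercased surface form, so inflected and nominal forms
# are listed explicitly where lemmatizers disagree.

found_in:
  - find
  - found
  - detect
  - detected
  - detection
  - localize
  - localized
  - localization
  - locate
  - located
  - observe
  - observed
  - present

movement:
  - translocate
  - translocation
  - recruit
  - relocate
  - relocalize
  - redistribute
  - shuttle
  - transport
  - traffic
  - move
  - migrate
  - import
  - export

event:
  - interact
  - interaction
  - express
  - expression
  - phosphorylate
  - phosphorylation
  - colocalize
  - colocalization
  - accumulate
  - accumulation
  - associate
  - bind
  - assemble
  - degrade
  - sequester
  - synthesize

part_whole_noun:
  - subunit
  - component
  - constituent
  - member

containment_verb:
  - contain
  - consist
  - comprise
  - include

detected_in:
  - detect
  - detected
  - observe
  - observed
  - find
  - found
  - identify
  - identified

formation:
  - form
  - formation
  - assemble
  - assembly
  - dimerize
  - dimerization
  - heterodimerize
  - heterodimerization
  - homodimerize
  - trimerize
  - oligomerize
  - oligomerization
  - multimerize
  - complex

ppi:
  - interact
  - bind
  - associate
  - coimmunoprecipitate
  - co-immunoprecipitate

stability_marker:
  - stable
  - stably
  - tight
  - tightly
  - constitutive
  - constitutively

staining:
  - stain
  - staining
  - immunostaining

tags:
  - GFP
  - EGFP
  - YFP
  - RFP
  - CFP
  - mCherry
  - HA
  - FLAG
  - His
  - Myc
  - V5
  - GST
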