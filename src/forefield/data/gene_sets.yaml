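# Default target gene-set definitions.
#
# A gene-coding region belongs to a set when its label matches any pattern
# (case-insensitive regular expression) OR its GO terms intersect go_ids.
# These vocabularies are configuration, not code: edit or replace this file
# to adapt the screen to a different annotation source.
nitrogenase:
  patterns:
    - "nitrogenase"
    - "\\bnif[HDK]\\b"
  go_ids:
    - "GO:0016163"   # nitrogenase activity
    - "GO:0009399"   # nitrogen fixation
obcA:
  patterns:
    - "obcA"
    - "oxalate biosynthetic component A"
  go_ids: []
cyanide_synthase:
  patterns:
    - "cyanide synthase"
    - "\\bhcn[ABC]\\b"
  go_ids: []
siderophore:
  patterns:
    - "siderophore"
  go_ids:
    - "GO:0019290"   # siderophore biosynthetic process
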