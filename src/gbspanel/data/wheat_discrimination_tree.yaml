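# Four-level hierarchical discrimination tree for common (Triticum aestivum,
# AABBDD) versus durum (T. turgidum, AABB) wheat and their subspecies.
# Contrast sides are matched against the "species:subspecies" taxon label.
# Node 1 splits the two species; A-branch nodes peel off aestivum subspecies,
# T-branch nodes peel off turgidum subspecies, one subspecies (or pair) at a
# time, down to the last distinguishable pair.
label_on: species_subspecies
nodes:
  - id: "1"
    parent: null
    side_a:
      - "T. aestivum:aestivum"
      - "T. aestivum:compactum"
      - "T. aestivum:sphaerococcum"
      - "T. aestivum:spelta"
    side_b:
      - "T. turgidum:carthlicum"
      - "T. turgidum:dicoccon"
      - "T. turgidum:durum"
      - "T. turgidum:polonicum"
      - "T. turgidum:turanicum"
      - "T. turgidum:turgidum"
  - id: "2A"
    parent: "1"
    side_a:
      - "T. aestivum:sphaerococcum"
    side_b:
      - "T. aestivum:aestivum"
      - "T. aestivum:compactum"
      - "T. aestivum:spelta"
  - id: "2T"
    parent: "1"
    side_a:
      - "T. turgidum:carthlicum"
      - "T. turgidum:dicoccon"
    side_b:
      - "T. turgidum:durum"
      - "T. turgidum:polonicum"
      - "T. turgidum:turanicum"
      - "T. turgidum:turgidum"
  - id: "2-2T"
    parent: "2T"
    side_a:
      - "T. turgidum:dicoccon"
    side_b:
      - "T. turgidum:carthlicum"
  - id: "3A"
    parent: "2A"
    side_a:
      - "T. aestivum:spelta"
    side_b:
      - "T. aestivum:aestivum"
      - "T. aestivum:compactum"
  - id: "3T"
    parent: "2T"
    side_a:
      - "T. turgidum:turgidum"
    side_b:
      - "T. turgidum:durum"
      - "T. turgidum:polonicum"
      - "T. turgidum:turanicum"
  - id: "4A"
    parent: "3A"
    side_a:
      - "T. aestivum:aestivum"
    side_b:
      - "T. aestivum:compactum"
  - id: "4T"
    parent: "3T"
    side_a:
      - "T. turgidum:durum"
    side_b:
      - "T. turgidum:polonicum"
      - "T. turgidum:turanicum"
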