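# Default immune-subset gating rules for the six-marker multiplex panel
# (CD3, CD4, CD20, CD21, CD103, BCL6).  A cell is assigned every subset whose
# required-positive markers are all 1 and required-negative markers all 0;
# labels are non-exclusive.
#
# The CD4 T-cell gates require CD3 co-positivity (the panel carries no CD8
# antibody and CD8 T cells are defined as CD3+CD4-; requiring CD3 excludes
# CD4+ myeloid cells).  Edit this file to use bare-CD4 gates instead.
- subset: cd4_t
  positive: [CD3, CD4]
- subset: cd8_t
  positive: [CD3]
  negative: [CD4]
- subset: b_cell
  positive: [CD20]
- subset: fdc
  positive: [CD21]
- subset: cd3_trm
  positive: [CD3, CD103]
- subset: cd4_trm
  positive: [CD3, CD4, CD103]
- subset: cd8_trm
  positive: [CD3, CD103]
  negative: [CD4]
- subset: gc_b
  positive: [CD20, BCL6]
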