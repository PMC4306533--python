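# Residue-numbering offsets, expressed as the shift that converts a
# convention INTO human eIF4E1a numbering.  XeIF4E1b numbering coincides
# with heIF4E1a; XeIF4E1a runs 4 residues behind both (Trp98 in XeIF4E1a is
# Trp102 in heIF4E1a / XeIF4E1b).
to_heIF4E1a:
  heIF4E1a: 0
  XeIF4E1b: 0
  XeIF4E1a: 4
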