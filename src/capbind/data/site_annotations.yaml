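# Functional-site annotation keyed to human eIF4E1a residue numbering.
# Editable: extend or correct as needed for other reference proteins.
# cap-pocket: residues stacking the 7-methylguanine, hydrogen-bonding the
# ring, or contacting the phosphate chain / C-terminal loop.
# partner-site: convex-face residues of helices H1/H2 contacting
# eIF4G/4E-BP-type partners.
sites:
  56: cap-pocket (Trp56 stacking)
  90: cap-pocket (Asp90 phosphate network)
  102: cap-pocket (Trp102 stacking)
  103: cap-pocket (Glu103 N1/N2 hydrogen bonds)
  112: cap-pocket (Arg112 phosphate)
  157: cap-pocket (Arg157 phosphate)
  162: cap-pocket (Lys162 phosphate)
  166: cap-pocket (Trp166 N7-methyl contact)
  200: cap-pocket (His200 benzyl vicinity)
  204: cap-pocket (C-terminal loop)
  205: cap-pocket (C-terminal loop)
  206: cap-pocket (C-terminal loop)
  207: cap-pocket (C-terminal loop)
  208: cap-pocket (C-terminal loop)
  209: cap-pocket (C-terminal loop)
  210: cap-pocket (C-terminal loop)
  211: cap-pocket (C-terminal loop)
  69: partner-site (H1 face)
  70: partner-site (H1 face)
  73: partner-site (Trp73, eIF4G/4E-BP anchor)
  131: partner-site (H2 face)
  135: partner-site (H2 face)
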