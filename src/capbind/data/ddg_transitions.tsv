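block	from_ligand	to_ligand
guanine_ring	GTP	m7GTP
guanine_ring	GTP	et7GTP
guanine_ring	m7GTP	et7GTP
guanine_ring	m7GDP	bn7GDP
guanine_ring	m7GTP	m2,2,7GTP
phosphate_chain	m7GMP	m7GDP
phosphate_chain	m7GDP	m7GTP
phosphate_chain	m7GTP	m7Gp4
phosphate_chain	m7Gp4	m7Gp5
second_nucleotide	m7GTP	m7GpppG
second_nucleotide	m7GTP	m7GpppA
second_nucleotide	m7GpppG	m7,2'OGpppG
second_nucleotide	m7GpppG	m7Gpppm2'OG
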