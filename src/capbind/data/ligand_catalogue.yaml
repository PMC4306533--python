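# Illustrative cap-analogue catalogue.
#
# pKa values here are ILLUSTRATIVE defaults drawn from general nucleotide
# chemistry (N1 proton of 7-methylguanosine near pH 7.2; secondary proton of
# a terminal phosphate near pH 6.5).  They are configuration, not measured
# constants: replace them with experimental values before quantitative
# charge-vs-pH work.  base_charge is the net charge with every listed group
# protonated.
ligands:
  - name: GTP
    base_charge: -3
    groups:
      - {label: "terminal phosphate -OH", pKa: 6.5, delta: -1}
  - name: m7GMP
    base_charge: 0
    groups:
      - {label: "N1-H (7-methylguanine)", pKa: 7.2, delta: -1}
      - {label: "terminal phosphate -OH", pKa: 6.3, delta: -1}
  - name: m7GDP
    base_charge: -1
    groups:
      - {label: "N1-H (7-methylguanine)", pKa: 7.2, delta: -1}
      - {label: "terminal phosphate -OH", pKa: 6.4, delta: -1}
  - name: m7GTP
    base_charge: -2
    groups:
      - {label: "N1-H (7-methylguanine)", pKa: 7.2, delta: -1}
      - {label: "terminal phosphate -OH", pKa: 6.5, delta: -1}
  - name: m7Gp4
    base_charge: -3
    groups:
      - {label: "N1-H (7-methylguanine)", pKa: 7.2, delta: -1}
      - {label: "terminal phosphate -OH", pKa: 6.5, delta: -1}
  - name: m7Gp5
    base_charge: -4
    groups:
      - {label: "N1-H (7-methylguanine)", pKa: 7.2, delta: -1}
      - {label: "terminal phosphate -OH", pKa: 6.5, delta: -1}
  - name: et7GTP
    base_charge: -2
    groups:
      - {label: "N1-H (7-ethylguanine)", pKa: 7.2, delta: -1}
      - {label: "terminal phosphate -OH", pKa: 6.5, delta: -1}
  - name: bn7GDP
    base_charge: -1
    groups:
      - {label: "N1-H (7-benzylguanine)", pKa: 7.1, delta: -1}
      - {label: "terminal phosphate -OH", pKa: 6.4, delta: -1}
  - name: m2,2,7GTP
    base_charge: -2
    groups:
      - {label: "N1-H (2,2,7-trimethylguanine)", pKa: 7.3, delta: -1}
      - {label: "terminal phosphate -OH", pKa: 6.5, delta: -1}
  - name: m7GpppG
    base_charge: -2
    groups:
      - {label: "N1-H (7-methylguanine)", pKa: 7.2, delta: -1}
  - name: m7GpppA
    base_charge: -2
    groups:
      - {label: "N1-H (7-methylguanine)", pKa: 7.2, delta: -1}
  - name: "m7Gpppm2'OG"
    base_charge: -2
    groups:
      - {label: "N1-H (7-methylguanine)", pKa: 7.2, delta: -1}
  - name: "m7,2'OGpppG"
    base_charge: -2
    groups:
      - {label: "N1-H (7-methylguanine)", pKa: 7.2, delta: -1}
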