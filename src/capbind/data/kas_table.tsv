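protein	ligand	buffer	kas_uM_inv	se	n
heIF4E1a	GTP	standard	0.027	0.001	1
heIF4E1a	m7GTP	standard	68.4	5.1	1
heIF4E1a	et7GTP	standard	13.04	0.31	1
heIF4E1a	bn7GDP	standard	16.79	0.56	1
heIF4E1a	m2,2,7GTP	standard	0.362	0.008	1
heIF4E1a	m7GMP	standard	0.78	0.04	1
heIF4E1a	m7GDP	standard	17.76	0.34	1
heIF4E1a	m7Gp4	standard	419	23	1
heIF4E1a	m7Gp5	standard	547	31	1
heIF4E1a	m7GpppG	standard	5.94	0.39	1
heIF4E1a	m7GpppA	standard	3.97	0.21	1
heIF4E1a	m7Gpppm2'OG	standard	4.77	0.13	1
heIF4E1a	m7,2'OGpppG	standard	6.13	0.34	1
heIF4E1b	GTP	standard	0.159	0.040	1
heIF4E1b	m7GTP	standard	22.0	1.4	1
heIF4E1b	et7GTP	standard	7.34	0.34	1
heIF4E1b	bn7GDP	standard	35.4	1.6	1
heIF4E1b	m2,2,7GTP	standard	0.272	0.009	1
heIF4E1b	m7GMP	standard	0.628	0.016	1
heIF4E1b	m7GDP	standard	7.64	0.71	1
heIF4E1b	m7Gp4	standard	89.6	4.0	1
heIF4E1b	m7Gp5	standard	146.6	9.9	1
heIF4E1b	m7GpppG	standard	3.53	0.11	1
heIF4E1b	m7GpppA	standard	2.158	0.053	1
heIF4E1b	m7Gpppm2'OG	standard	3.568	0.071	1
heIF4E1b	m7,2'OGpppG	standard	4.63	0.12	1
XeIF4E1a	GTP	standard	0.031	0.006	1
XeIF4E1a	m7GTP	standard	42.8	2.0	1
XeIF4E1a	et7GTP	standard	7.89	0.57	1
XeIF4E1a	bn7GDP	standard	10.62	0.98	1
XeIF4E1a	m2,2,7GTP	standard	0.295	0.021	1
XeIF4E1a	m7GMP	standard	0.567	0.012	1
XeIF4E1a	m7GDP	standard	11.42	0.50	1
XeIF4E1a	m7Gp4	standard	268	10	1
XeIF4E1a	m7Gp5	standard	378	44	1
XeIF4E1a	m7GpppG	standard	3.98	0.11	1
XeIF4E1a	m7GpppA	standard	2.015	0.028	1
XeIF4E1a	m7GTP	glycerol10	23.34	0.88	1
XeIF4E1a	et7GTP	glycerol10	4.97	0.22	1
XeIF4E1a	bn7GDP	glycerol10	6.04	0.92	1
XeIF4E1a	m2,2,7GTP	glycerol10	0.176	0.011	1
XeIF4E1a	GTP	glycerol10	0.055	0.021	1
XeIF4E1a	m7GMP	glycerol10	0.256	0.018	1
XeIF4E1a	m7GDP	glycerol10	5.97	0.37	1
XeIF4E1a	m7Gp4	glycerol10	151.1	8.6	1
XeIF4E1a	m7Gp5	glycerol10	230	31	1
XeIF4E1a	m7GpppG	glycerol10	2.291	0.065	1
XeIF4E1a	m7GpppA	glycerol10	1.22	0.053	1
XeIF4E1a	m7Gpppm2'OG	glycerol10	2.189	0.026	1
XeIF4E1a	m7,2'OGpppG	glycerol10	1.96	0.24	1
XeIF4E1bdN27	m7GTP	glycerol10	7.80	0.41	1
XeIF4E1bdN27	et7GTP	glycerol10	2.26	0.20	1
XeIF4E1bdN27	bn7GDP	glycerol10	4.36	0.18	1
XeIF4E1bdN27	m2,2,7GTP	glycerol10	0.253	0.046	1
XeIF4E1bdN27	m7GDP	glycerol10	2.43	0.15	1
XeIF4E1bdN27	m7Gp4	glycerol10	43.0	2.0	1
XeIF4E1bdN27	m7Gp5	glycerol10	65.6	4.2	1
XeIF4E1bdN27	m7GpppG	glycerol10	0.883	0.032	1
XeIF4E1bdN27	m7GpppA	glycerol10	0.615	0.042	1
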