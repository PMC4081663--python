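#reference=GGGACTTTCC
#name=NF-kB p50 SNMM (bimolecular dsDNA microarray)
base	1	2	3	4	5	6	7	8	9	10
A	-31.69	-36.06	-21.42	0.00	4.67	-26.26	-32.82	-27.38	-14.68	-28.07
C	-32.96	-40.34	-33.63	-32.27	0.00	-33.02	-28.05	8.13	0.00	0.00
G	0.00	0.00	0.00	-3.12	3.03	-27.83	-20.37	-33.97	-29.88	-28.17
T	-30.00	-32.43	-6.66	-24.15	5.74	0.00	0.00	0.00	-23.25	-32.61
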