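# isotope abundance table, version nist-2017.1 (normalized per element)
element	mass_number	mass_Da	abundance
H	1	1.0078250321	0.999885000000
H	2	2.0141017778	0.000115000000
C	12	12.0000000000	0.989300000000
C	13	13.0033548378	0.010700000000
N	14	14.0030740048	0.996360000000
N	15	15.0001088982	0.003640000000
O	16	15.9949146196	0.997570000000
O	17	16.9991317000	0.000380000000
O	18	17.9991610000	0.002050000000
P	31	30.9737616300	1.000000000000
S	32	31.9720710000	0.949900000000
S	33	32.9714587600	0.007500000000
S	34	33.9678669000	0.042500000000
S	36	35.9670807600	0.000100000000
Se	74	73.9224764000	0.008900000000
Se	76	75.9192136000	0.093700000000
Se	77	76.9199140000	0.076300000000
Se	78	77.9173091000	0.237700000000
Se	80	79.9165213000	0.496100000000
Se	82	81.9166994000	0.087300000000
Na	23	22.9897692809	1.000000000000
K	39	38.9637066800	0.932581000000
K	40	39.9639984800	0.000117000000
K	41	40.9618257600	0.067302000000
Cl	35	34.9688526800	0.757600000000
Cl	37	36.9659025900	0.242400000000
Si	28	27.9769265325	0.922230000000
Si	29	28.9764947000	0.046850000000
Si	30	29.9737701700	0.030920000000
Br	79	78.9183371000	0.506900000000
Br	81	80.9162906000	0.493100000000
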