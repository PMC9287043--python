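# element	isotope_mass_Da	abundance
# IUPAC 2013 representative isotopic compositions; rows sorted by mass within element.
H	1.00782503207	0.999885
H	2.01410177785	0.000115
C	12.0	0.9893
C	13.00335483507	0.0107
N	14.00307400443	0.99636
N	15.00010889888	0.00364
O	15.99491461957	0.99757
O	16.99913175650	0.00038
O	17.99915961286	0.00205
S	31.9720711744	0.9499
S	32.9714589098	0.0075
S	33.9678670040	0.0425
S	35.9670807100	0.0001
P	30.97376199842	1.0
F	18.99840316273	1.0
Na	22.98976928200	1.0
I	126.90447190000	1.0
Cl	34.96885268200	0.7576
Cl	36.96590260200	0.2424
Br	78.91833760000	0.5069
Br	80.91628970000	0.4931
K	38.96370648640	0.932581
K	39.96399816600	0.000117
K	40.96182525790	0.067302
Si	27.97692653465	0.92223
Si	28.97649466490	0.04685
Si	29.97377013600	0.03092
Se	73.92247593400	0.0089
Se	75.91921370400	0.0937
Se	76.91991415400	0.0763
Se	77.91730928000	0.2377
Se	79.91652180000	0.4961
Se	81.91669950000	0.0873
Fe	53.93960899000	0.05845
Fe	55.93493633000	0.91754
Fe	56.93539284000	0.02119
Fe	57.93327443000	0.00282
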