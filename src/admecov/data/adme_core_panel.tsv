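gene	rsid	chrom	pos
CYP3A5	rs776746	7	99270539
CYP3A5	rs10264272	7	99262835
CYP3A5	rs41279854	7	99247772
CYP3A5	rs41303343	7	99250393
CYP3A5	rs55965422	7	99264573
CYP3A4	rs2242480	7	99361466
CYP3A4	rs4646438	7	99364034
CYP3A4	rs55785340	7	99365983
CYP3A4	rs67666821	7	99355806
CYP2D6	rs1065852	22	42526694
CYP2D6	rs1080985	22	42528382
CYP2D6	rs3892097	22	42524947
CYP2D6	rs5030655	22	42525086
CYP2D6	rs5030656	22	42524178
CYP2D6	rs5030862	22	42526670
CYP2D6	rs5030863	22	42539583
CYP2D6	rs5030865	22	42525035
CYP2D6	rs5030867	22	42523858
CYP2D6	rs28371706	22	42525772
CYP2D6	rs28371725	22	42523805
CYP2D6	rs35742686	22	42524244
CYP2D6	rs72549346	22	42523534
CYP2D6	rs72549347	22	42527305
CYP2D6	rs72549349	22	42523843
CYP2D6	rs72549351	22	42524206
CYP2D6	rs72549352	22	42524214
CYP2D6	rs72549353	22	42527956
CYP2D6	rs72549354	22	42524820
CYP2D6	rs72549357	22	42526657
CYP2C8	rs1058930	10	96818119
CYP2C8	rs10509681	10	96798749
CYP2C8	rs11572103	10	96818106
CYP2C8	rs72558195	10	96824643
CYP2C8	rs72558197	10	96826973
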