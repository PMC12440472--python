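rsid	Omni1S:direct	Omni2.5S:direct	Omni2.5:direct	Omni5:direct	Axiom:direct	Omni1S:ld	Omni2.5S:ld	Omni2.5:ld	Omni5:ld	Axiom:ld
rs776746	0	0	1	1	1	0	0	1	1	1
rs10264272	0	0	1	1	1	0	0	1	1	1
rs41279854	0	0	0	0	1	0	0	0	0	1
rs41303343	0	0	0	0	1	0	0	0	0	1
rs55965422	0	1	0	1	1	0	1	0	1	1
rs2242480	1	1	1	1	1	1	1	1	1	1
rs4646438	0	0	0	0	0	0	1	0	1	0
rs55785340	0	0	0	0	1	0	0	0	0	1
rs67666821	0	0	0	0	0	0	1	0	1	1
rs1065852	0	0	0	0	1	0	0	0	0	1
rs1080985	0	0	0	0	1	0	0	0	0	1
rs3892097	0	0	0	0	1	0	0	0	0	1
rs5030655	0	0	0	0	1	0	0	0	0	1
rs5030656	0	0	0	0	0	0	0	1	0	1
rs5030862	0	1	0	1	0	0	1	0	1	0
rs5030863	0	0	0	0	0	0	1	0	1	1
rs5030865	0	0	0	0	0	1	1	1	1	1
rs5030867	0	0	0	0	1	0	0	0	0	1
rs28371706	0	0	0	0	1	0	0	0	0	1
rs28371725	0	0	0	1	1	0	0	0	1	1
rs35742686	0	0	0	0	1	0	0	0	0	1
rs72549346	0	0	0	0	0	0	1	0	1	1
rs72549347	0	0	0	0	0	0	1	0	1	1
rs72549349	0	0	0	0	0	0	1	0	1	1
rs72549351	0	0	0	0	0	0	1	0	1	1
rs72549352	0	0	0	0	0	0	0	0	0	0
rs72549353	0	0	0	0	0	0	1	0	1	1
rs72549354	0	0	0	0	0	0	1	1	1	1
rs72549357	0	0	0	0	0	0	0	0	0	0
rs1058930	0	0	1	1	1	0	0	1	1	1
rs10509681	0	1	0	0	1	0	1	0	0	1
rs11572103	0	0	1	1	1	0	0	1	1	1
rs72558195	0	0	0	0	0	0	0	1	1	1
rs72558197	0	0	0	0	0	0	0	1	1	1
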