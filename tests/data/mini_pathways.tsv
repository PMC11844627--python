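MitoPathway	MitoPathways Hierarchy	Genes
OXPHOS	OXPHOS	M01, M02, M03, M04, M05, M06, M07, M08, M09, M10, M11, M12
Complex I	OXPHOS > Complex I	M01, M02, M03, M04, M05, M06, M07, M08
CI subunits	OXPHOS > Complex I > CI subunits	M01, M02, M03, M04, M05
CI assembly factors	OXPHOS > Complex I > CI assembly factors	M06, M07, M08
Complex III	OXPHOS > Complex III	M09, M10, M11, M12
Metabolism	Metabolism	M13, M14, M15, M16, M17, M18, M19, M20, M21, M22, M23, M24, M25, M26, M27, M28, M29, M30
Fatty acid oxidation	Metabolism > Fatty acid oxidation	M13, M14, M15, M16, M17, M18, M19, M20, M21, M22
Urea cycle	Metabolism > Urea cycle	M13, M23, M24, M25, M26, M27, M28, M29, M30
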