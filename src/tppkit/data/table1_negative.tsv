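# adduct is not part of the published table; [M+FA-H]- marks the two rows whose
# printed m/z matches the formate adduct of the printed formula (within 1 ppm)
# rather than [M-H]-.
name	formula	mz	rt_min	mzvault_score	sample_control_ratio	ion_mode	adduct
N-Acetylglutamic acid	C7H11NO5	188.05663	1.403	88.6	29.27	negative	[M-H]-
Forsythoside E	C20H30O12	461.16685	5.795	88.3	43.39	negative	[M-H]-
Hastatoside	C17H24O11	449.13039	5.972	84.3	40.19	negative	[M+FA-H]-
Atractyloside A	C21H36O10	493.22952	6.266	90.5	40.27	negative	[M+FA-H]-
Purpureaside C	C35H46O20	785.25233	7.471	90.2	50.63	negative	[M-H]-
Vicenin II	C27H30O15	593.15181	7.583	89.5	33.36	negative	[M-H]-
Dihydromorin	C15H12O7	303.05097	7.886	92.0	104.08	negative	[M-H]-
Isoforsythiaside	C29H36O15	623.19852	8.252	91.1	109.93	negative	[M-H]-
Magnoloside A	C29H36O15	623.19843	9.288	89.2	83.28	negative	[M-H]-
Apigenin 5-O-glucoside	C21H20O10	431.09853	9.289	89.2	29.35	negative	[M-H]-
Narirutin	C27H32O14	579.17223	9.721	90.9	43.45	negative	[M-H]-
Isoacteoside	C29H36O15	623.19834	9.724	88.6	109.99	negative	[M-H]-
Rosmarinic acid	C18H16O8	359.07738	10.035	82.8	97.41	negative	[M-H]-
Salvianolic acid A	C26H22O10	493.11453	10.062	89.3	31.69	negative	[M-H]-
Puerarin	C21H20O9	415.10377	10.097	84.2	85.09	negative	[M-H]-
Hesperetin	C16H14O6	301.07183	10.225	92.8	40.93	negative	[M-H]-
Scutellarin	C21H18O12	461.07282	10.605	84.9	32.96	negative	[M-H]-
Baicalein	C15H10O5	269.04536	10.82	91.0	20.02	negative	[M-H]-
Oroxin A	C21H20O10	431.09846	11.188	88.1	35.62	negative	[M-H]-
Dalbergioidin	C15H12O6	287.05634	11.239	84.8	150.86	negative	[M-H]-
Baicalin	C21H18O11	445.07751	11.446	87.1	33.5	negative	[M-H]-
Luteolin	C15H10O6	285.04062	11.773	87.2	23.75	negative	[M-H]-
Oroxylin A	C16H12O5	283.06125	11.788	90.4	24.75	negative	[M-H]-
Didymin	C28H34O14	593.18798	12.009	90.1	33.26	negative	[M-H]-
Wogonoside	C22H20O11	459.093	12.188	91.5	24.93	negative	[M-H]-
Hexahydrocurcumin	C21H26O6	373.1659	12.613	85.4	30.01	negative	[M-H]-
Hispidulin	C16H12O6	299.0562	12.707	89.2	36.79	negative	[M-H]-
Randaiol	C15H14O3	241.08724	13.291	80.8	152.77	negative	[M-H]-
Formononetin	C16H12O4	267.06628	13.61	88.7	49.0	negative	[M-H]-
Magnaldehyde D	C16H14O3	253.0871	14.129	84.2	81.1	negative	[M-H]-
Wogonin	C16H12O5	283.0611	14.291	89.9	23.53	negative	[M-H]-
Casticin	C19H18O8	373.0929	14.435	80.1	109.01	negative	[M-H]-
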