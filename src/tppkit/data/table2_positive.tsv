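name	formula	mz	rt_min	mzvault_score	sample_control_ratio	ion_mode
Hordenine	C10H15NO	166.1224	2.271	86.3	31.83	positive
Indoleacrylic acid	C11H9NO2	188.0704	5.299	84.4	35.78	positive
Vicenin II	C27H30O15	595.16551	7.568	86	45.71	positive
N-Methylcoclaurine	C18H21NO3	300.15912	7.754	89.6	21.01	positive
Scutellarein	C15H10O6	287.05462	8.886	81.2	26.26	positive
Calycosin-7-O-β-d-glucoside	C22H22O10	447.12807	8.968	82.9	25.81	positive
Naringenin	C15H12O5	273.07539	9.718	89.1	38.50	positive
Narirutin	C27H32O14	581.18599	9.718	89.8	35.54	positive
Hesperetin	C16H14O6	303.08563	10.229	89.8	42.68	positive
Hesperidin	C28H34O15	611.19639	10.231	89.4	34.81	positive
Baicalein	C15H10O5	271.05936	10.828	83.4	23.90	positive
Baicalin	C21H18O11	447.09099	10.829	80.5	24.28	positive
Atractylenolide I	C15H18O2	231.1376	11.217	83.9	31.00	positive
Formononetin	C16H12O4	269.08048	11.229	84.7	21.53	positive
Jatrorrhizine	C20H19NO4	338.13782	11.237	90.1	22.20	positive
Oroxylin A	C16H12O5	285.07512	11.791	83.1	27.36	positive
Calycosin	C16H12O5	285.07516	11.931	92.5	22.71	positive
Wogonin	C16H12O5	285.07495	12.195	82	24.61	positive
Heterophyllin B	C40H58N8O8	779.44451	13.048	90.1	35.10	positive
Isosinensetin	C20H20O7	373.12749	13.374	93.1	46.46	positive
5-O-Demethylnobiletin	C20H20O8	389.12254	13.532	87.7	55.67	positive
Sinensetin	C20H20O7	373.12687	13.853	90	48.41	positive
6-Demethoxytangeretin	C19H18O6	343.11711	13.93	85.5	38.92	positive
Nobiletin	C21H22O8	403.13754	14.363	92.8	30.35	positive
Tangeretin	C20H20O7	373.1272	14.909	90.9	49.55	positive
Curcumenol	C15H22O2	235.16861	14.924	91.1	31.01	positive
Zederone	C15H18O3	247.13265	15.203	84.3	31.31	positive
Dihydrotanshinone I	C18H14O3	279.10093	15.657	87	48.06	positive
Cryptotanshinone	C19H20O3	297.1477	16.609	87.7	104.72	positive
Tanshinone IIA	C19H18O3	295.13229	17.508	93	33.04	positive
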