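# ion_mode is not part of the published table; it is inferred per row from which
# [M+H]+ / [M-H]- adduct of the printed formula matches the printed m/z within 5 ppm.
name	formula	mz	rt_min	ion_mode
Epiberberine	C20H17NO4	336.12263	12.735	positive
Palmatine	C21H21NO4	352.15407	12.696	positive
Jatrorrhizine	C20H19NO4	338.13866	11.872	positive
(+)-Magnoflorine	C20H23NO4	342.16997	8.584	positive
Berberrubine	C19H15NO4	322.10752	10.559	positive
Demethyleneberberine	C19H17NO4	324.12316	10.732	positive
Nobiletin	C21H22O8	403.13876	15.267	positive
Sinensetin	C20H20O7	373.12831	14.714	positive
Formononetin	C16H12O4	269.08093	14.401	positive
Dehydroglaucine	C21H23NO4	354.16999	11.123	positive
6-Demethoxytangeretin	C19H18O6	343.11792	15.312	positive
Quinic acid	C7H12O6	191.05673	1.02	negative
Oroxylin A-7-O-β-d-glucuronide	C22H20O11	459.09442	13.101	negative
TF-Hesperidin	C28H34O15	609.184	11.383	negative
Narirutin	C27H32O14	579.17336	10.778	negative
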