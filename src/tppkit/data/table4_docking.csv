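chemspider_id,compound,xp_gscore,mmgbsa_dg_bind
390871,Narirutin,-6.114,-34.20
65269,Jatrorrhizine,-2.447,-22.11
402990,Berberrubine,-2.200,-31.28
128491,Sinensetin,-1.373,-30.91
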