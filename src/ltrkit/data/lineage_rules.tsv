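# Expected structural features per lineage.
# chromodomain: comma list of allowed values among CHD,CHDCR,none (or "any")
# arh_position: comma list among none,PROT_RT,RH_INT,after_INT (or "any")
# pbs: comma list of tokens mode[:isoacceptor]; "full:*" = any complete tRNA;
#      a fuzzy call counts as its full-tRNA token; mode "none" never flags.
lineage	chromodomain	arh_position	pbs
Ty1/copia|Ale	none	none	full:tRNA-Met
Ty1/copia|Alesia	none	none	full:tRNA-Met
Ty1/copia|Angela	none	none	full:tRNA-Met
Ty1/copia|Bianca	none	none	half:tRNA-Ile
Ty1/copia|Bryco	none	none	half:tRNA-Met
Ty1/copia|Gymco-I	none	none	full:tRNA-Met
Ty1/copia|Gymco-II	none	none	half:tRNA-Met,full:tRNA-Met
Ty1/copia|Gymco-III	none	none	full:tRNA-Met
Ty1/copia|Gymco-IV	none	none	full:tRNA-Met
Ty1/copia|Ikeros	none	none	full:tRNA-Met
Ty1/copia|Ivana	none	none	full:tRNA-Met
Ty1/copia|Lyco	none	none	full:tRNA-Met
Ty1/copia|Osser	none	none	half:tRNA-Met
Ty1/copia|SIRE	none	none	full:tRNA-Met
Ty1/copia|TAR	none	none	self
Ty1/copia|Tork	none	none	full:tRNA-Met
Ty3/gypsy|chromovirus|CRM	CHD,CHDCR,none	none	full:tRNA-Met
Ty3/gypsy|chromovirus|Chlamyvir	CHD,none	none	full:tRNA-Met
Ty3/gypsy|chromovirus|Galadriel	CHD,none	none	full:tRNA-Met
Ty3/gypsy|chromovirus|Reina	CHD,none	none	full:tRNA-Met
Ty3/gypsy|chromovirus|Tekay	CHD,none	none	full:tRNA-Met
Ty3/gypsy|chromovirus|Tcn1	CHD,none	none	self
Ty3/gypsy|non-chromovirus|OTA|Athila	none	none	full:tRNA-Ala,full:tRNA-Arg,full:tRNA-Asp,full:tRNA-Lys,full:tRNA-Trp,full:tRNA-Asn
Ty3/gypsy|non-chromovirus|OTA|Tat|TatI	none	PROT_RT	full:tRNA-Ala,full:tRNA-Arg,full:tRNA-Asp,full:tRNA-Lys,full:tRNA-Trp,full:tRNA-Asn
Ty3/gypsy|non-chromovirus|OTA|Tat|TatII	none	PROT_RT	full:tRNA-Ala,full:tRNA-Arg,full:tRNA-Asp,full:tRNA-Lys,full:tRNA-Trp,full:tRNA-Asn
Ty3/gypsy|non-chromovirus|OTA|Tat|TatIII	none	after_INT	full:tRNA-Ala,full:tRNA-Arg,full:tRNA-Asp,full:tRNA-Lys,full:tRNA-Trp,full:tRNA-Asn
Ty3/gypsy|non-chromovirus|OTA|Tat|Ogre	none	RH_INT	full:tRNA-Ala,full:tRNA-Arg,full:tRNA-Asp,full:tRNA-Lys,full:tRNA-Trp,full:tRNA-Asn
Ty3/gypsy|non-chromovirus|OTA|Tat|Retand	none	RH_INT	full:tRNA-Ala,full:tRNA-Arg,full:tRNA-Asp,full:tRNA-Lys,full:tRNA-Trp,full:tRNA-Asn
Ty3/gypsy|non-chromovirus|Phygy	none	none	any
Ty3/gypsy|non-chromovirus|Selgy	none	none	any
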