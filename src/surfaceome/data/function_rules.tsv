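# Ordered function-category rules: first match wins.
# kind	pattern	category
keyword	methyl-accepting chemotaxis	CHEMOTAXIS
keyword	chemotaxis	CHEMOTAXIS
keyword	flagell	CHEMOTAXIS
keyword	pilus	CHEMOTAXIS
keyword	pilin	CHEMOTAXIS
keyword	ABC transporter	TRANSPORT
keyword	TRAP transporter	TRANSPORT
keyword	transporter	TRANSPORT
keyword	permease	TRANSPORT
keyword	symporter	TRANSPORT
keyword	antiporter	TRANSPORT
keyword	solute binding	TRANSPORT
keyword	solute-binding	TRANSPORT
keyword	substrate binding	TRANSPORT
keyword	efflux	TRANSPORT
keyword	secretion	TRANSPORT
keyword	ferredoxin	REDOX
keyword	oxidoreductase	REDOX
keyword	reductase	REDOX
keyword	hydrogenase	REDOX
keyword	4Fe-4S	REDOX
keyword	peptidase	PROTEASE_CW_HYDROLASE
keyword	protease	PROTEASE_CW_HYDROLASE
keyword	hydrolase	PROTEASE_CW_HYDROLASE
keyword	penicillin-binding	PROTEASE_CW_HYDROLASE
keyword	lysozyme	PROTEASE_CW_HYDROLASE
accession	PF07833	PROTEASE_CW_HYDROLASE
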