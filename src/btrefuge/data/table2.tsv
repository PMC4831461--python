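species	crop	toxin	country	gen_per_year	q0	qj	Tj
Busseola fusca	Corn	Cry1Ab	South Africa	2		>0.1	<16
Diatraea saccharalis	Corn	Cry1Ab	USA	4-5	0.0023	0.018	27
Helicoverpa armigera	Cotton	Cry1Ac	China	3-5	0.0058	0.075	36
Helicoverpa armigera	Cotton	Cry2Ab	Australia	3-5	0.0033	0.021	28
Helicoverpa punctigera	Cotton	Cry2Ab	Australia	3-5	0.0010	0.0091	28
Helicoverpa zea	Cotton	Cry1Ac	USA	3	0.0008	>0.1	<18
Helicoverpa zea	Cotton	Cry2Ab	USA	3	0.0004	>0.1	<12
Ostrinia furnacalis	Corn	Cry1Ab	Philippines	6		>0.1	36
Pectinophora gossypiella	Cotton	Cry1Ac	China	3		>0.1	39
Pectinophora gossypiella	Cotton	Cry1Ac	India	4-6		>0.1	<30
Spodoptera frugiperda	Corn	Cry1F	USA	10		>0.1	<30
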