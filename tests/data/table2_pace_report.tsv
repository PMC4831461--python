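species	crop	toxin	country	gen_per_year	q0	q0_assumed	qj	qj_censored	Tj	xi_star	xi_is_lower_bound	Tk_star	years_to_qk
Busseola fusca	Corn	Cry1Ab	South Africa	2	0.001	True	0.1	True	16	0.294346	True	NA	NA
Diatraea saccharalis	Corn	Cry1Ab	USA	4.5	0.0023	False	0.018	False	27	0.0767898	False	50.4666	11.2148
Helicoverpa armigera	Cotton	Cry1Ac	China	4	0.0058	False	0.075	False	36	0.0731049	False	40.31	10.0775
Helicoverpa armigera	Cotton	Cry2Ab	Australia	4	0.0033	False	0.021	False	28	0.0667328	False	52.6473	13.1618
Helicoverpa punctigera	Cotton	Cry2Ab	Australia	4	0.001	False	0.0091	False	28	0.0791577	False	59.4955	14.8739
Helicoverpa zea	Cotton	Cry1Ac	USA	3	0.0008	False	0.1	True	18	0.274049	True	NA	NA
Helicoverpa zea	Cotton	Cry2Ab	USA	3	0.0004	False	0.1	True	12	0.468868	True	NA	NA
Ostrinia furnacalis	Corn	Cry1Ab	Philippines	6	0.001	True	0.1	True	36	0.13082	True	NA	NA
Pectinophora gossypiella	Cotton	Cry1Ac	China	3	0.001	True	0.1	True	39	0.120757	True	NA	NA
Pectinophora gossypiella	Cotton	Cry1Ac	India	5	0.001	True	0.1	True	30	0.156984	True	NA	NA
Spodoptera frugiperda	Corn	Cry1F	USA	10	0.001	True	0.1	True	30	0.156984	True	NA	NA
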