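ID	coef	HR	HR.95L	HR.95H	p_value
AC105460.1|AL590483.1	0.434869442	1.544761365	0.972868122	2.45283777	0.065275621
AP001469.3|AL137782.1	1.173749307	3.234095554	1.349471659	7.750717832	0.008487151
LINC00941|AL590483.1	0.412896035	1.511187907	0.968800939	2.357232325	0.068723513
AP001453.2|AC027796.4	-0.773706228	0.461300212	0.284593551	0.747725607	0.001691186
AC007128.1|AL590483.1	0.704647609	2.023133626	1.276459379	3.206580434	0.002711144
AC124067.4|SNHG7	-0.467395261	0.626632358	0.39248827	1.000458211	0.050224749
LINC00513|AC010973.2	-0.801575511	0.448621599	0.279579346	0.719871986	0.000893026
LINC00513|LENG8-AS1	-0.518086862	0.595659037	0.324938192	1.091929779	0.093828869
FENDRR|NKILA	-0.781365548	0.457780463	0.299833856	0.698930252	0.000295668
AL451050.2|AL137782.1	0.544271131	1.723351826	1.046348925	2.838385406	0.032522231
AL137782.1|AL354993.2	-0.554021701	0.57463415	0.367625261	0.898209241	0.015056368
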