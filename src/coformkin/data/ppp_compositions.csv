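ppp,formulation_type,substance,function,content_g_per_kg,ppp_rate_kg_per_ha,water_l_per_ha,rate_override_g_per_ha,trial
Armicarb-vegetables,SP,docusate,surfactant,88,3,800,263,vegetables
Armicarb-vegetables,SP,SDS,surfactant,62,3,800,168,vegetables
Flint-vegetables,WG,trifloxystrobin,fungicide,514,0.4,800,,vegetables
Flint-vegetables,WG,DBNS,surfactant,47,0.4,800,19,vegetables
Input-vegetables,EC,spiroxamine,fungicide,300,1.25,800,,vegetables
Input-vegetables,EC,DMDA,solvent,396,1.25,800,,vegetables
Armicarb-apples,SP,docusate,surfactant,72,4.8,400,,apples
Armicarb-apples,SP,SDS,surfactant,54,4.8,400,257,apples
Flint-apples,WG,trifloxystrobin,fungicide,502,0.24,400,,apples
Flint-apples,WG,DBNS,surfactant,47,0.24,400,,apples
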