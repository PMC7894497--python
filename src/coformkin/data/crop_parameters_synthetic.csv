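crop,soil_coverage,plant_weight_kg,plants_per_ha,whole_plant_commodity
leaf lettuce,0.80,0.25,90000,True
head lettuce,0.85,0.35,72000,True
parsley,0.90,0.05,440000,True
celery,0.70,0.45,100000,True
rondini,0.95,1.5,10000,False
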