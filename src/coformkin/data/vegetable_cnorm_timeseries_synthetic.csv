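crop,substance,day,c_norm_mg_kg
leek,DMDA,0,0.52
leek,DMDA,3,0.0052
leek,DMDA,14,0.0052
leek,docusate,0,5.5
leek,docusate,3,0.825
leek,docusate,14,0.165
leek,SDS,0,3.4
leek,SDS,3,0.51
leek,SDS,14,0.102
leek,DBNS,0,4.0
leek,DBNS,3,0.60
leek,DBNS,14,0.12
leek,spiroxamine,0,2.3
leek,spiroxamine,3,0.759
leek,spiroxamine,14,0.138
leek,trifloxystrobin,0,3.9
leek,trifloxystrobin,3,1.833
leek,trifloxystrobin,14,0.234
leaf lettuce,DMDA,0,6.5
leaf lettuce,DMDA,3,0.065
leaf lettuce,DMDA,14,0.065
leaf lettuce,docusate,0,23
leaf lettuce,docusate,3,3.45
leaf lettuce,docusate,14,0.69
leaf lettuce,SDS,0,12
leaf lettuce,SDS,3,1.8
leaf lettuce,SDS,14,0.36
leaf lettuce,DBNS,0,21
leaf lettuce,DBNS,3,3.15
leaf lettuce,DBNS,14,0.63
leaf lettuce,spiroxamine,0,16
leaf lettuce,spiroxamine,3,5.28
leaf lettuce,spiroxamine,14,0.96
leaf lettuce,trifloxystrobin,0,29
leaf lettuce,trifloxystrobin,3,13.63
leaf lettuce,trifloxystrobin,14,1.74
head lettuce,DMDA,0,11
head lettuce,DMDA,3,0.11
head lettuce,DMDA,14,0.11
head lettuce,docusate,0,28
head lettuce,docusate,3,4.2
head lettuce,docusate,14,0.84
head lettuce,SDS,0,19
head lettuce,SDS,3,2.85
head lettuce,SDS,14,0.57
head lettuce,DBNS,0,34
head lettuce,DBNS,3,5.1
head lettuce,DBNS,14,1.02
head lettuce,spiroxamine,0,28
head lettuce,spiroxamine,3,9.24
head lettuce,spiroxamine,14,1.68
head lettuce,trifloxystrobin,0,37
head lettuce,trifloxystrobin,3,17.39
head lettuce,trifloxystrobin,14,2.22
parsley,DMDA,0,18
parsley,DMDA,3,11.16
parsley,DMDA,14,3.24
parsley,docusate,0,39
parsley,docusate,3,5.85
parsley,docusate,14,1.17
parsley,SDS,0,34
parsley,SDS,3,5.1
parsley,SDS,14,1.02
parsley,DBNS,0,41
parsley,DBNS,3,6.15
parsley,DBNS,14,1.23
parsley,spiroxamine,0,14
parsley,spiroxamine,3,4.62
parsley,spiroxamine,14,0.84
parsley,trifloxystrobin,0,31
parsley,trifloxystrobin,3,14.57
parsley,trifloxystrobin,14,1.86
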