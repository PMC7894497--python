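trial,crop,substance,c0_mg_kg,c0_norm_printed,consistent
vegetables,leek,DMDA,0.26,0.52,False
vegetables,leek,docusate,1.5,5.5,False
vegetables,leek,SDS,0.6,3.4,False
vegetables,leek,DBNS,0.08,4.0,False
vegetables,leek,spiroxamine,0.87,2.3,True
vegetables,leek,trifloxystrobin,0.80,3.9,True
vegetables,leaf lettuce,DMDA,3.2,6.5,True
vegetables,leaf lettuce,docusate,6.0,23,True
vegetables,leaf lettuce,SDS,2.2,12,False
vegetables,leaf lettuce,DBNS,0.40,21,True
vegetables,leaf lettuce,spiroxamine,6.1,16,True
vegetables,leaf lettuce,trifloxystrobin,6.0,29,True
vegetables,head lettuce,DMDA,5.4,11,True
vegetables,head lettuce,docusate,7.4,28,True
vegetables,head lettuce,SDS,3.5,19,False
vegetables,head lettuce,DBNS,0.65,34,True
vegetables,head lettuce,spiroxamine,10.6,28,True
vegetables,head lettuce,trifloxystrobin,7.5,37,False
vegetables,parsley,DMDA,9.0,18,True
vegetables,parsley,docusate,10,39,False
vegetables,parsley,SDS,6.3,34,False
vegetables,parsley,DBNS,0.78,41,True
vegetables,parsley,spiroxamine,5.3,14,True
vegetables,parsley,trifloxystrobin,6.5,31,False
vegetables,celery,DMDA,8.6,17,True
vegetables,celery,docusate,7.3,28,True
vegetables,celery,SDS,3.7,20,False
vegetables,celery,DBNS,0.49,26,True
vegetables,celery,spiroxamine,4.8,13,True
vegetables,celery,trifloxystrobin,4.8,23,True
apples,apples,docusate,0.40,1.2,True
apples,apples,SDS,0.20,0.8,False
apples,apples,DBNS,0.012,1.1,True
apples,apples,trifloxystrobin,0.14,1.1,False
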