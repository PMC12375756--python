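graph_id,drug,M1,M2,FN,ND3,ND5,NH,NI
G0,Actinomycin D,1162,32946,17606,46982,212.1012,16.6743,278.8874
G1,Anastrozole,264,17100,1616,9456,49.85,4.1949,63.9522
G2,Cabozantinib,480,56816,3008,18274,87.0143,7.3764,116.9891
G3,Cyclophosphamide,144,5040,848,4828,30.3167,3.0851,34.6277
G4,Doxorubicin,550,74104,3816,25474,94.8679,7.1905,132.5252
G5,Etoposide,604,90115,4052,26682,102.271,8.0812,147.4245
G6,Gemcitabine,232,13132,1552,9792,42.2075,3.3285,55.5364
G7,Ibandronate,202,9717,1330,7774,40.4366,3.5539,47.3827
G8,Ifosfamide,144,5040,848,4844,30.1833,3.093,34.6892
G9,Letrozole,262,16905,1536,8928,50.4429,4.6634,64.1327
G10,Pazopanib,404,40228,2522,15046,72.3321,5.8765,98.357
G11,Regorafenib,390,37496,2288,12932,74.0571,6.5007,95.1728
G12,Sorafenib,374,34528,2160,12066,71.4952,6.3829,91.4764
G13,Tamoxifen,316,24640,1810,10462,62.4611,6.0734,77.5096
G14,Zoledronic acid,196,9163,1358,8360,35.8561,2.7695,46.1692
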