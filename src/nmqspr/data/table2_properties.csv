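graph_id,drug,BP,EV,FP,MR,SA,P,ST,MV
G0,Actinomycin D,1386,211.5,792.1,323.7,356,128.3,53.9,880.7
G1,Anastrozole,469.7,73.2,237.9,90,78,35.7,42.2,270.3
G2,Cabozantinib,758.1,110.4,412.3,137,99,54.3,67.5,359
G3,Cyclophosphamide,336.1,57.9,157.1,58.1,51,23,44.3,195.3
G4,Doxorubicin,810.3,123.5,443.8,131.5,206,52.1,96.4,336.6
G5,Etoposide,798.1,121.7,263.6,140.1,161,55.5,76.5,378.5
G6,Gemcitabine,482.7,86.2,245.7,52.1,108,20.6,65.3,142.3
G7,Ibandronate,587.8,100.7,309.3,68.9,158,27.3,70.8,220.2
G8,Ifosfamide,336.1,57.9,157.1,58.1,51,23,44.3,195.7
G9,Letrozole,563.5,84.7,294.6,87.1,78,34.5,53.5,234.5
G10,Pazopanib,728.8,106.4,394.6,120.2,127,47.6,56.7,310.4
G11,Regorafenib,513.4,78.5,264.3,113.1,92,44.8,50.8,323.7
G12,Sorafenib,523.3,79.7,270.3,113.1,92,44.8,51.8,319.5
G13,Tamoxifen,482.3,74.7,140,118.9,12,47.1,40.4,356.2
G14,Zoledronic acid,764,116.7,415.8,50.3,173,19.9,149.7,127.4
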