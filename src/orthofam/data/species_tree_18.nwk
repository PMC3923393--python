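(((((((((Hsa:0.35,(Cin:0.25,Bfl:0.2):0.1):0.1,Spu:0.4):0.1,Dme:0.5):0.15,Nve:0.6):0.1,Tad:0.65):0.1,Aqe:0.7):0.15,(Mbr:0.4,Sro:0.4):0.4):0.1,((Cow:0.6,Sar:0.6):0.15,((Sce:0.3,Spo:0.3):0.2,(Cci:0.4,Spn:0.4):0.1):0.3):0.2):0.2,(Ttr:0.9,Ddi:1.0):0.2);
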