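id,role,ic50_um,mw,logp,logs,caco2_nm_s,max_known_similarity
Y27632,control,0.17,247.34,1.46,-2.28,218.77,0.39
TS-f5,hit,1.55,281.36,2.34,-2.88,160.88,0.34
TS-f6,hit,12.4,360.22,2.17,-3.65,59.20,0.36
TS-f7,hit,28.3,375.48,1.73,-3.17,12.75,0.20
TS-f10,hit,31.35,363.38,2.20,-4.33,352.91,0.21
TS-f13,hit,3.2,334.40,3.27,-4.69,602.73,0.41
TS-f22,hit,0.48,248.29,3.38,-4.36,1548.30,0.36
TS-f25,hit,4.42,279.30,2.66,-3.64,1633.03,0.35
TS-f26,hit,3.48,276.30,2.78,-4.49,687.51,0.36
TS-f28,hit,23.05,296.13,3.11,-2.97,560.11,0.31
TS-f32,hit,2.21,283.33,3.17,-4.78,804.27,0.41
TS-f37,hit,1.82,304.35,3.97,-5.03,1436.03,0.34
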