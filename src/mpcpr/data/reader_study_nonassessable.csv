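reader,modality,n_segments,total,percent
1,mpcpr,44,888,5.0
1,axial,76,888,8.6
2,mpcpr,25,888,2.8
2,axial,29,888,3.3
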