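region,modality,percent,numerator,denominator,discrepant
iliac,mpcpr,94,85,90,0
iliac,axial,88,76,86,0
femoro-popliteal,mpcpr,89,359,405,0
femoro-popliteal,axial,86,335,389,0
infra-popliteal,mpcpr,93,324,344,1
infra-popliteal,axial,94,312,330,1
overall,mpcpr,92,768,839,0
overall,axial,90,725,805,0
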