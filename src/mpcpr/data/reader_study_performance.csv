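region,reader,modality,statistic,percent,numerator,denominator,discrepant
iliac,1,mpcpr,sensitivity,82,9,11,0
iliac,1,axial,sensitivity,90,9,10,0
iliac,2,mpcpr,sensitivity,83,10,12,0
iliac,2,axial,sensitivity,100,12,12,0
iliac,1,mpcpr,specificity,95,75,79,0
iliac,1,axial,specificity,88,67,76,0
iliac,2,mpcpr,specificity,99,79,80,0
iliac,2,axial,specificity,95,77,81,0
iliac,1,mpcpr,accuracy,93,84,90,0
iliac,1,axial,accuracy,88,76,86,0
iliac,2,mpcpr,accuracy,97,89,92,0
iliac,2,axial,accuracy,96,89,93,0
iliac,1,mpcpr,ppv,69,9,13,0
iliac,1,axial,ppv,50,9,18,0
iliac,2,mpcpr,ppv,91,10,11,0
iliac,2,axial,ppv,75,12,16,0
iliac,1,mpcpr,npv,97,75,77,0
iliac,1,axial,npv,99,67,68,0
iliac,2,mpcpr,npv,98,79,81,0
iliac,2,axial,npv,100,77,77,0
femoro-popliteal,1,mpcpr,sensitivity,85,74,87,0
femoro-popliteal,1,axial,sensitivity,86,74,86,0
femoro-popliteal,2,mpcpr,sensitivity,82,75,91,0
femoro-popliteal,2,axial,sensitivity,88,82,93,0
femoro-popliteal,1,mpcpr,specificity,95,305,320,0
femoro-popliteal,1,axial,specificity,88,271,308,0
femoro-popliteal,2,mpcpr,specificity,88,300,321,1
femoro-popliteal,2,axial,specificity,92,295,321,0
femoro-popliteal,1,mpcpr,accuracy,93,379,407,0
femoro-popliteal,1,axial,accuracy,88,345,394,0
femoro-popliteal,2,mpcpr,accuracy,91,375,412,0
femoro-popliteal,2,axial,accuracy,91,377,414,0
femoro-popliteal,1,mpcpr,ppv,83,74,89,0
femoro-popliteal,1,axial,ppv,67,74,111,0
femoro-popliteal,2,mpcpr,ppv,78,75,96,0
femoro-popliteal,2,axial,ppv,76,82,108,0
femoro-popliteal,1,mpcpr,npv,96,305,318,0
femoro-popliteal,1,axial,npv,96,271,283,0
femoro-popliteal,2,mpcpr,npv,98,300,306,0
femoro-popliteal,2,axial,npv,96,295,306,0
infra-popliteal,1,mpcpr,sensitivity,95,137,144,0
infra-popliteal,1,axial,sensitivity,99,138,140,0
infra-popliteal,2,mpcpr,sensitivity,94,142,151,0
infra-popliteal,2,axial,sensitivity,95,143,150,0
infra-popliteal,1,mpcpr,specificity,92,186,203,0
infra-popliteal,1,axial,specificity,92,176,192,0
infra-popliteal,2,mpcpr,specificity,99,206,208,0
infra-popliteal,2,axial,specificity,99,199,202,0
infra-popliteal,1,mpcpr,accuracy,93,323,347,0
infra-popliteal,1,axial,accuracy,95,314,332,0
infra-popliteal,2,mpcpr,accuracy,97,348,359,0
infra-popliteal,2,axial,accuracy,97,342,352,0
infra-popliteal,1,mpcpr,ppv,89,137,154,0
infra-popliteal,1,axial,ppv,90,138,154,0
infra-popliteal,2,mpcpr,ppv,99,142,144,0
infra-popliteal,2,axial,ppv,98,143,146,0
infra-popliteal,1,mpcpr,npv,96,177,184,0
infra-popliteal,1,axial,npv,99,175,177,0
infra-popliteal,2,mpcpr,npv,96,206,215,0
infra-popliteal,2,axial,npv,97,199,206,0
overall,1,mpcpr,sensitivity,91,220,242,0
overall,1,axial,sensitivity,94,221,236,0
overall,2,mpcpr,sensitivity,89,227,254,0
overall,2,axial,sensitivity,93,237,255,0
overall,1,mpcpr,specificity,94,566,602,0
overall,1,axial,specificity,89,514,576,0
overall,2,mpcpr,specificity,96,585,609,0
overall,2,axial,specificity,95,571,604,0
overall,1,mpcpr,accuracy,93,786,844,0
overall,1,axial,accuracy,91,735,812,0
overall,2,mpcpr,accuracy,94,812,863,0
overall,2,axial,accuracy,94,808,859,0
overall,1,mpcpr,ppv,86,220,256,0
overall,1,axial,ppv,78,221,283,0
overall,2,mpcpr,ppv,90,227,251,0
overall,2,axial,ppv,88,237,270,0
overall,1,mpcpr,npv,96,539,560,0
overall,1,axial,npv,98,511,524,0
overall,2,mpcpr,npv,96,585,612,0
overall,2,axial,npv,97,571,589,0
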