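# Predicted ADMET descriptor set for the library 4a-4o and reference
# standards: BBB level 0-4, absorption level 0-3, binary hepatotoxicity and
# CYP2D6 inhibition, plasma protein binding, log solubility level, AlogP98,
# 2D polar surface area.
compound_id,bbb_level,absorption_level,hepatotoxicity,cyp2d6,ppb,log_solubility,alogp98,psa_2d
4a,1,0,0,0,true,-5.186,3.932,54.725
4b,1,0,0,1,true,-5.896,4.596,54.725
4c,2,0,0,0,false,-4.686,3.690,75.541
4d,1,0,0,0,true,-5.199,3.915,63.655
4e,1,0,0,0,true,-5.972,4.680,54.725
4f,4,0,0,0,true,-5.326,3.826,97.548
4g,4,0,0,0,true,-5.350,3.826,97.548
4h,1,0,0,1,true,-5.668,4.418,54.725
4i,1,0,0,0,true,-6.449,5.166,54.725
4j,2,0,0,0,true,-5.162,4.176,75.541
4k,4,0,0,0,true,-5.818,4.312,97.548
4l,2,0,0,0,true,-5.141,4.176,75.541
4m,1,0,0,1,true,-6.374,5.082,54.725
4n,1,0,0,0,true,-5.671,4.402,63.655
4o,4,0,0,0,true,-5.793,4.312,97.548
Alpidem,0,0,0,0,true,-6.455,5.729,37.262
Ciprofloxacin,3,0,0,0,false,-3.162,1.435,74.932
GSK812397,2,0,0,0,true,-3.910,2.621,58.743
minodronic acid,4,3,0,0,false,-1.462,0.098,155.288
miroprofen,2,0,0,0,true,-3.750,2.905,54.725
necopidem,0,0,0,0,true,-6.072,5.130,37.262
olprinone,3,0,0,0,false,-2.255,0.509,69.655
saripidem,1,0,0,0,true,-5.174,4.114,37.262
zolimidine,2,0,0,0,true,-3.812,2.304,51.210
zolpidem,1,0,0,0,true,-4.984,3.628,37.262
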