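# Docking score table for the library 4a-4o and the reference standard
# minodronic acid against farnesyl diphosphate synthase (FDPS).
ligand_id,target_id,moldock,rerank,interaction_energy,steric,hbond,is_reference
4a,FDPS,-121.070,-46.2331,-129.523,-125.412,-4.12665,False
4b,FDPS,-116.882,-86.3746,-127.038,-123.787,-3.25102,False
4c,FDPS,-119.894,-92.4212,-131.989,-126.252,-5.73747,False
4d,FDPS,-121.378,-92.2706,-133.879,-130.228,-3.65058,False
4e,FDPS,-116.694,-86.3413,-126.942,-123.758,-3.18489,False
4f,FDPS,-124.997,-82.7741,-139.449,-130.422,-11.7324,False
4g,FDPS,-136.382,-97.9987,-148.481,-139.207,-9.27341,False
4h,FDPS,-121.380,-91.9035,-131.591,-129.897,-5.74383,False
4i,FDPS,-115.326,-78.1772,-126.461,-119.791,-6.66971,False
4j,FDPS,-123.665,-94.6358,-134.444,-128.501,-5.94368,False
4k,FDPS,-145.600,-107.580,-149.188,-136.328,-12.8601,False
4l,FDPS,-126.914,-97.9745,-138.142,-133.722,-8.41212,False
4m,FDPS,-117.557,-89.4801,-128.437,-124.994,-3.44365,False
4n,FDPS,-125.239,-94.7880,-136.104,-132.444,-3.65975,False
4o,FDPS,-125.450,-87.6107,-135.379,-124.855,-10.5236,False
minodronic acid,FDPS,-111.023,-88.7053,-117.088,-97.5360,-19.5515,True
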