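# Docking score table for the library 4a-4o and the reference standard
# olprinone against phosphodiesterase 3B (PDE3B).
ligand_id,target_id,moldock,rerank,interaction_energy,steric,hbond,is_reference
4a,PDE3B,-108.136,-32.3135,-125.473,-118.475,-6.99816,False
4b,PDE3B,-111.562,-78.3614,-120.628,-116.517,-4.11087,False
4c,PDE3B,-119.362,-89.9521,-128.679,-124.015,-4.66410,False
4d,PDE3B,-116.080,-79.6175,-125.506,-120.981,-4.52482,False
4e,PDE3B,-111.031,-77.0171,-120.362,-116.213,-4.14992,False
4f,PDE3B,-118.320,-83.1092,-128.576,-119.230,-9.34526,False
4g,PDE3B,-130.663,-98.3234,-141.452,-132.962,-8.49026,False
4h,PDE3B,-109.303,-73.0475,-118.408,-114.611,-3.79774,False
4i,PDE3B,-115.557,-85.9591,-123.242,-119.762,-3.48020,False
4j,PDE3B,-118.900,-87.8734,-126.795,-120.784,-6.01043,False
4k,PDE3B,-128.312,-81.8875,-132.019,-122.726,-9.29270,False
4l,PDE3B,-116.616,-65.0245,-127.611,-118.031,-9.58031,False
4m,PDE3B,-115.537,-85.9622,-123.216,-119.743,-3.47298,False
4n,PDE3B,-126.841,-94.7604,-130.499,-122.702,-7.79698,False
4o,PDE3B,-125.361,-94.0195,-131.192,-126.334,-8.55344,False
olprinone,PDE3B,-105.404,-82.9526,-116.144,-112.107,-4.03755,True
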