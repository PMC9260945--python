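# Predicted toxicity probabilities for the library 4a-4o, as published
# ("label (p)" cell format).
compound_id,rat_male_ntp,mouse_male_ntp,ames_mutagenicity,skin_irritation,aerobic_biodegradability
4a,non-carcinogen (0.000),non-carcinogen (0.000),non-mutagen (0.000),non-irritant (0.000),non-biodegradable (0.000)
4b,non-carcinogen (0.000),non-carcinogen (0.000),non-mutagen (0.000),non-irritant (0.000),non-biodegradable (0.000)
4c,non-carcinogen (0.010),non-carcinogen (0.000),non-mutagen (0.000),non-irritant (0.000),non-biodegradable (0.000)
4d,non-carcinogen (0.000),non-carcinogen (0.000),non-mutagen (0.000),non-irritant (0.000),non-biodegradable (0.000)
4e,non-carcinogen (0.001),non-carcinogen (0.000),non-mutagen (0.094),non-irritant (0.000),non-biodegradable (0.000)
4f,non-carcinogen (0.001),non-carcinogen (0.000),non-mutagen (0.022),non-irritant (0.000),non-biodegradable (0.000)
4g,non-carcinogen (0.000),non-carcinogen (0.000),non-mutagen (0.000),non-irritant (0.003),non-biodegradable (0.131)
4h,non-carcinogen (0.000),non-carcinogen (0.000),non-mutagen (0.000),non-irritant (0.000),biodegradable (1.000)
4i,non-carcinogen (0.000),non-carcinogen (0.000),non-mutagen (0.000),non-irritant (0.002),non-biodegradable (0.000)
4j,non-carcinogen (0.001),non-carcinogen (0.000),non-mutagen (0.002),non-irritant (0.000),non-biodegradable (0.000)
4k,non-carcinogen (0.000),non-carcinogen (0.000),non-mutagen (0.000),non-irritant (0.030),non-biodegradable (0.000)
4l,non-carcinogen (0.000),non-carcinogen (0.000),non-mutagen (0.000),non-irritant (0.000),non-biodegradable (0.000)
4m,non-carcinogen (0.009),non-carcinogen (0.000),non-mutagen (0.000),irritant (0.992),non-biodegradable (0.000)
4n,non-carcinogen (0.001),non-carcinogen (0.000),non-mutagen (0.008),non-irritant (0.000),non-biodegradable (0.002)
4o,non-carcinogen (0.000),non-carcinogen (0.000),non-mutagen (0.000),non-irritant (0.000),non-biodegradable (0.016)
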