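variant,mutations,tm,tm_err
FGF21-WT,,44.4,0.05
FGF21-E58P,E58P,47.3,0.12
FGF21-E65P,E65P,44.6,0.05
FGF21-D74Y,D74Y,45.6,0.17
FGF21-A109W,A109W,47.7,0.24
FGF21-D117N,D117N,50.3,0.11
FGF21-Q136V,Q136V,53.4,0.36
FGF21-E138L,E138L,43.3,0.08
FGF21-Q104M,Q104M,51.0,0.16
FGF21-A139K,A139K,49.0,0.12
FGF21-K150R,K150R,48.4,0.27
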