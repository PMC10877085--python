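variant,mutations,tm,tm_err
FGF21-WT,,44.4,0.05
FGF21-3PM,Q104M+A139K+K150R,54.8,0.12
FGF21-4PM,Q104M+A139K+K150R+Q136V,59.6,0.26
FGF21-5PM,Q104M+A139K+K150R+Q136V+A109W,58.1,0.08
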