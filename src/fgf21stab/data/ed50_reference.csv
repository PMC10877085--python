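cell_line,variant,ed50_ng_ml
NIH3T3,FGF21-WT,38.0
NIH3T3,FGF21-3PM,15.9
NIH3T3,FGF21-4PM,18.0
HepG2,FGF21-WT,8.7
HepG2,FGF21-3PM,11.3
HepG2,FGF21-4PM,24.9
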