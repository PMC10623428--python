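name,formula,adduct,printed_mz,note
Xanthurenic acid 8-O-sulfate,C10H7NO7S,M+Na,307.97,computed 307.9835; ~40 ppm from the reported value; annotation tentative
Xanthurenic acid 8-O-sulfate,C10H7NO7S,M+2Na-H,329.95,computed 329.9655; ~46 ppm from the reported value; annotation tentative
IMP,C10H13N4O8P,M+K,387.01,
PA C36:3,C39H71O8P,M+K,737.45,
PA C38:5,C41H71O8P,M+K,761.45,
PA C38:4,C41H73O8P,M+K,763.46,computed 763.4675; rounds to 763.47; within ~10 ppm of the reported value
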