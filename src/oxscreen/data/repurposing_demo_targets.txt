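SGT01
SGT02
SGT03
SGT04
SGT05
SGT06
SGT07
SGT08
SGT09
SGT10
SGT11
SGT12
SGT13
SGT14
SGT15
SGT16
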