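INT01
INT02
INT03
INT04
INT05
INT06
INT07
INT08
INT09
INT10
INT11
INT12
INT13
INT14
INT15
INT16
INT17
INT18
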