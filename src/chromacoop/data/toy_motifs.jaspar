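>ERE ERE_toy
A [ 1 1 1 1 37 10 10 10 1 1 37 1 1 ]
C [ 1 1 1 37 1 10 10 10 1 1 1 37 37 ]
G [ 37 37 1 1 1 10 10 10 1 37 1 1 1 ]
T [ 1 1 37 1 1 10 10 10 37 1 1 1 1 ]
>HSE HSE_toy
A [ 1 1 1 10 10 1 37 37 10 10 1 1 1 ]
C [ 1 1 37 10 10 1 1 1 10 10 1 1 37 ]
G [ 1 1 1 10 10 37 1 1 10 10 1 1 1 ]
T [ 37 37 1 10 10 1 1 1 10 10 37 37 1 ]
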