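>ISRE_SYN synthetic canonical ISRE stand-in (consensus NGAAANTGAAACT)
A  [ 40  2 94 94 94 25  2  2 94 94 94  2  2 ]
C  [ 10  2  2  2  2 25  2  2  2  2  2 94  2 ]
G  [ 40 94  2  2  2 25  2 94  2  2  2  2  2 ]
T  [ 10  2  2  2  2 25 94  2  2  2  2  2 94 ]
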