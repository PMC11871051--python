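12
t=0.0 preset=S0 labels=N1,C2,N3,C4,C5,C6,S,O,H9,H10,H11,H12
N -0.769308 -1.097196 0.000000
C -1.353398 0.139458 0.000000
N -0.505293 1.210459 0.000000
C 0.861961 1.126074 0.000000
C 1.423328 -0.240559 0.000000
C 0.586937 -1.281642 0.000000
S -2.986663 0.444115 0.000000
O 1.591814 2.110037 0.000000
H -1.389132 -1.902183 0.000000
H -0.900661 2.139247 0.000000
H 2.500022 -0.340028 0.000000
H 0.940393 -2.307781 0.000000
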