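code_a,code_b,n_both,n_a_only,n_b_only,n_neither,p_value
F84,F70,,,,,0.0001
F84,F80,,,,,0.0001
F84,G40,400,600,300,8700,
F84,R56,,,,,0.001
F84,F90,,,,,0.0005
F84,F95,,,,,0.01
F84,G47,,,,,0.02
F84,R62,,,,,0.03
G40,R56,500,200,400,8900,
F70,F80,,,,,0.002
F70,R56,,,,,0.04
F70,G40,,,,,0.01
F80,F90,,,,,0.02
E58.x,E61.1,,,,,0.01
E58.x,E60.x,,,,,0.02
E61.1,E60.x,,,,,0.03
F84,E58.x,,,,,0.04
F84,E61.1,,,,,0.06
F84,J06,,,,,0.30
F84,J02,,,,,0.60
J00,J02,,,,,0.001
J02,J03,,,,,0.002
F84,J32.9,,,,,0.04
F84,L20.8,,,,,0.20
L20.8,L30.9,,,,,0.01
F84,D64.9,,,,,0.50
F84,K59,,,,,0.04
F84,F41,,,,,0.30
F84,R94,,,,,0.70
F84,R50.9,,,,,0.03
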