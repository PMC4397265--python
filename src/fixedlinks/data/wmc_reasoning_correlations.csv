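,Figural,Numerical,Verbal,Cond1,Cond2,Cond3,Cond4,Cond5
Figural,1.00,.58,.40,.36,.28,.41,.43,.34
Numerical,.58,1.00,.42,.27,.28,.40,.40,.32
Verbal,.40,.42,1.00,.17,.15,.27,.21,.15
Cond1,.36,.27,.17,1.00,.38,.52,.39,.42
Cond2,.28,.28,.15,.38,1.00,.56,.45,.42
Cond3,.41,.40,.27,.52,.56,1.00,.55,.49
Cond4,.43,.40,.21,.39,.45,.55,1.00,.53
Cond5,.34,.32,.15,.42,.42,.49,.53,1.00
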