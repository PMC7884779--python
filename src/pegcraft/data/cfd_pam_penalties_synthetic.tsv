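# Synthetic stand-in PAM-tail penalties (NGG -> 1.0; non-canonical
# tails heavily penalised; absent tails score 0).
pam_tail	penalty
AA	0.0
AC	0.0
AG	0.2593
AT	0.0
CA	0.0
CC	0.0
CG	0.1071
CT	0.0
GA	0.0694
GC	0.0217
GG	1.0
GT	0.0159
TA	0.0
TC	0.0
TG	0.0389
TT	0.0
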