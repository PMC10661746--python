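drug,ed50_mg_kg,sem_mg_kg,n_probit
CBZ,9.52,,16
PHT,8.71,,16
PB,28.85,,16
VPA,292,,24
ISOP,235.7,23.5,28
BOR,250,,16
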