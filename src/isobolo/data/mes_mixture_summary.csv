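combination,ed50_exp_total,sem_exp,n_exp,ed50_add_total,sem_add,n_add
CBZ + ISOP (25),33.44,0.84,16,33.51,2.33,44
CBZ + ISOP (50),57.32,0.97,24,57.50,3.54,44
PHT + ISOP (25),32.27,0.72,16,32.79,2.42,44
PHT + ISOP (50),56.13,0.67,24,56.86,3.61,44
PB + ISOP (25),51.17,2.07,16,50.79,2.84,44
PB + ISOP (50),74.67,2.16,24,72.73,3.99,44
VPA + ISOP (25),311.13,11.73,24,286.00,7.62,52
VPA + ISOP (50),313.8,10.15,32,280.0,8.19,52
CBZ + ISOP (25) + BOR (25),55.73,0.89,24,57.50,3.54,44
PHT + ISOP (25) + BOR (25),55.54,0.82,24,56.86,3.61,44
PB + ISOP (25) + BOR (25),62.25,2.52,24,72.73,3.99,44
VPA + ISOP (25) + BOR (25),218.9,13.15,24,280.0,8.19,52
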