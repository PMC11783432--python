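# Published two-peaked Weibull parameters for Synanthedon bicingulata adult
# flight in Korea (degree-days at LDT 4 C, biofix October 1 previous year).
alpha1: 0.4008
beta1: 1464.09
gamma1: -4.9041
delta_beta: 1829.17
gamma2: 189.73
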