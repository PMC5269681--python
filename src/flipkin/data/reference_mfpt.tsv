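system	tau_plus_s	tau_minus_s
# Published mean first passage times for the thymine-dimer flipping reaction
# (intra -> extra and back): isolated B-DNA, enzyme-deformed DNA, and the
# photolyase-bound complex, for the damaged (CPD) and undamaged (TT) step.
CPD_BDNA	3.8e1	1.7e-6
TT_BDNA	2.0e1	4.6e-7
CPD_1TEZ	4.5e-3	1.9e-7
TT_1TEZ	1.6e-1	5.2e-7
CPD_prot	1.2e-4	1.7e-2
TT_prot	3.9e-3	3.7e-3
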