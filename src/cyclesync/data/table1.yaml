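# Default operating point of the coupled N-cell cycle oscillator.
alpha1: 0.1
alpha2: 3
alpha3: 3
beta1: 3
beta2: 1
beta3: 1
K1: 0.5
K2: 0.5
K3: 0.5
n1: 4
n2: 4
n3: 4
n: 3
k0: 2
Ka: 0.5
km: 1.5
k: 1
KL: 0.5
N: 10
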