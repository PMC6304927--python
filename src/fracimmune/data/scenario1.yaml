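# Immune collapse: T-cell proliferative power at carrying capacity is
# negative, E1 (pathogen-only) is LAS; formal E2 has T* < 0.
name: scenario1
beta_P: 2.4
Lambda: 1
c: 4
a: 0.2
mu: 3.98
nu: 1.9
delta: 1.99
alpha1: 9/10
alpha2: 3/4
P0: 0.3
T0: 0.01
t_end: 400
h: 0.01
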