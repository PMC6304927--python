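# Sustained oscillation: E2 exists but violates the sector condition
# (min root angle ~14.32 deg < 18 deg); limit-cycle behaviour.
name: scenario2
beta_P: 2.4
Lambda: 10
c: 4
a: 4
mu: 3.9
nu: 1.9
delta: 1
alpha1: 4/5
alpha2: 3/5
P0: 0.3
T0: 0.01
t_end: 400
h: 0.01
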