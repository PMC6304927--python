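# Chronic coexistence: E2 = (0.5, 0.81) is LAS (min root angle
# ~22.03 deg > 18 deg); trajectories settle onto it.
name: scenario3
beta_P: 2.4
Lambda: 5
c: 4
a: 1
mu: 3.9
nu: 1.9
delta: 1
alpha1: 4/5
alpha2: 3/5
P0: 0.3
T0: 0.01
t_end: 300
h: 0.01
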