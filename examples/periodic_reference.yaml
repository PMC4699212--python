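# Deterministic reference simulation: argmax classification produces
# periodic switching between integration and segregation.
gamma: 0.1
eta: 0.5
delta: 5.0
sigma: 1.0
beta: 1.5
pi2_init: 0.001
mode: deterministic
n_phases: 60
max_elements: 200000
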