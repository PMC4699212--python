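# Reference stochastic simulation: slow updates, heavy-tailed classes,
# K-counter switching.  Produces phase statistics comparable to report data.
gamma: 0.03
eta: 0.1
delta: 0.6
sigma: 1.0
beta: 0.5
K: 6
pi2_init: 0.0001
mode: stochastic
n_phases: 3144
max_elements: 500000
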