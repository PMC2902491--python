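# Positively skewed four-parameter-beta severity (skewness +0.0883)
alpha0: -1.0
beta0: 2.5
alpha1: -20.0
beta1: 0.75
s11: 1.0
s22: 0.2
s12: 0.2
scale: 30.0
a: 70.0
b: 130.0
p_x: 0.03
n_subjects: 200
n_occasions: 50
n_reps: 200
seed: 1
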