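# Study parameter set for the TCD-IL2-Z tumor-immune model (unitless rates;
# the timescale of the source study is never stated).
alpha: 0.0514
beta: 1.02e-9
gamma: 0.1
phi: 1.0e-7
kappa: 0.02
mu: 480.0
rho: 1.0e-8
omega: 0.24
lambda_il2: 2.0e-7
d: 3.0e-4
a: 0.04
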