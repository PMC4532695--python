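# Plausible-demo parameter set (synthetic): physiologically ordered values
# chosen to satisfy every schema invariant.  NOT a literature transcription —
# use dafilis2013 for anything meant to correspond to published dynamics.

[membrane]
h_e_rest = -68.0
h_i_rest = -68.0
h_e_eq = 40.0
h_i_eq = -85.0
tau_e = 50.0
tau_i = 30.0

[synaptic]
Gamma_ee = 0.5
Gamma_ei = 0.5
Gamma_ie = 0.8
Gamma_ii = 0.8
gamma_ee = 0.25
gamma_ei = 0.25
gamma_ie = 0.08
gamma_ii = 0.08

[sigmoid]
S_e_max = 0.4
S_i_max = 0.4
mu_e = -48.0
mu_i = -48.0
sigma_e = 6.0
sigma_i = 6.0

[connectivity]
N_ee = 2500.0
N_ei = 2500.0
N_ie = 500.0
N_ii = 500.0

[inputs]
p_ee = 5.0
p_ei = 2.0
p_ie = 0.0
p_ii = 0.0
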