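# Standard physiological parameterization of the macrocolumnar Liley model
# (the canonical values of the model family: Liley, Cadusch & Dafilis lineage),
# with (Gamma, gamma) pairs tied by synapse source type: excitatory (ee = ei)
# and inhibitory (ie = ii).  Units: mV, ms, ms^-1; counts dimensionless.
#
# TRANSCRIPTION STATUS: intended as the parameter set of the published
# four-dimensional-chaos analyses of this model (Dafilis et al., Chaos
# 23:023111, 2013), whose exact table is not reproduced here.  Recomputing the
# Lyapunov spectrum at the reference inputs below with THIS set yields a
# stable limit cycle, not the published chaotic spectrum, so the
# correspondence is UNVERIFIED and results conditioned on it should be read
# accordingly (see docs/methods.md).

[membrane]
h_e_rest = -70.0
h_i_rest = -70.0
h_e_eq = 45.0
h_i_eq = -90.0
tau_e = 94.0
tau_i = 42.0

[synaptic]
Gamma_ee = 0.71
Gamma_ei = 0.71
Gamma_ie = 0.71
Gamma_ii = 0.71
gamma_ee = 0.3
gamma_ei = 0.3
gamma_ie = 0.065
gamma_ii = 0.065

[sigmoid]
S_e_max = 0.5
S_i_max = 0.5
mu_e = -50.0
mu_i = -50.0
sigma_e = 5.0
sigma_i = 5.0

[connectivity]
N_ee = 3034.0
N_ei = 3034.0
N_ie = 536.0
N_ii = 536.0

[inputs]
# Reference point of the four-dimensional-chaos study (white-circle point):
p_ee = 24.2453
p_ei = 2.299
p_ie = 0.0
p_ii = 0.0
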