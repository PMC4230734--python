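# sleepcortex parameter preset: n2
# N2: sigma_e = 4.6 mV, g_KNa = 1.33 mS/cm^2 (regime table of the source model). Region I close to the relaxation-cycle border; canard-mediated K-complexes.
# Units: mV, ms, mM, mS/cm^2; rates in s^-1; noise intensity in s^-1*sqrt(ms).
# Values not specific to a sleep stage follow the Compte-type cortical
# modeling lineage of sodium-adaptation neural mass models.

# -- excitatory (pyramidal) population --
excitatory.Qmax = 30.0            # maximal firing rate (s^-1)
excitatory.theta = -58.5          # firing threshold (mV)
excitatory.sigma = 4.6           # inverse gain (mV) -- bifurcation parameter
excitatory.sigmoid_scale = 1.8137993642342178   # pi/sqrt(3): sigma equals the SD of the logistic rate curve
excitatory.tau = 30.0             # membrane time constant (ms)
excitatory.E_leak = -66.0         # leak reversal (mV)

# -- inhibitory interneuron population --
inhibitory.Qmax = 60.0
inhibitory.theta = -58.5
inhibitory.sigma = 6.0
inhibitory.sigmoid_scale = 1.8137993642342178
inhibitory.tau = 30.0
inhibitory.E_leak = -64.0

# -- synapses (alpha-function kinetics) --
synapses.gamma_ampa = 70.0        # inverse rise time (s^-1)
synapses.gamma_gaba = 58.6        # inverse rise time (s^-1)
synapses.g_ampa = 1.0             # maximal conductivity (mS/cm^2)
synapses.g_gaba = 1.0
synapses.E_ampa = 0.0             # Nernst potential (mV)
synapses.E_gaba = -70.0
synapses.N_ee = 120.0             # mean connection counts (all-to-all coupling)
synapses.N_ei = 72.0
synapses.N_ie = 90.0
synapses.N_ii = 90.0
synapses.N_bg_e = 30.0            # background pathway onto excitatory population (package calibration)
synapses.N_bg_i = 30.0            # background pathway onto inhibitory population (package calibration)

# -- I_KNa adaptation and sodium pump --
adaptation.g_KNa = 1.33          # maximal K(Na) conductivity (mS/cm^2) -- bifurcation parameter
adaptation.E_K = -100.0           # potassium Nernst potential (mV)
adaptation.C_m = 1.0              # membrane capacity (uF/cm^2)
adaptation.alpha_Na = 2.0         # sodium influx per spike (mM ms)
adaptation.tau_Na = 1.5           # sodium balance time scale (ms; package calibration within lineage)
adaptation.R_pump = 0.09          # maximal pump rate (mM/ms)
adaptation.Na_eq = 9.5            # pump equilibrium concentration (mM)
adaptation.Na_half = 15.0         # pump half-saturation (mM)
adaptation.w_max = 0.37           # I_KNa gating saturation
adaptation.Na_gate = 38.7         # gating half-activation (mM)
adaptation.gate_exponent = 3.5    # gating Hill exponent

# -- background drive --
noise.phi_mean = 0.0              # zero-mean background fluctuations
noise.phi_sd = 400.0              # pathway white-noise intensity (s^-1*sqrt(ms); package calibration)
noise.stimulus_offset = 0.0       # set by stimulus protocols at run time
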