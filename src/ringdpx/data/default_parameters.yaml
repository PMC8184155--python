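# Default cellular / synaptic / drive parameters for the ring-attractor model.
# Units: mV, ms, nF, uS (gL_nS entries are nS and converted on load), kHz, mM.
version: "1.0"

pyramidal:
  cell:
    Cm: 0.50        # nF
    gL_nS: 25.0     # nS -> 0.025 uS
    V_L: -70.0
    V_th: -50.0
    V_rest: -60.0
    tau_ref: 2.0
  receptors:
    g_NMDA: 0.37        # uS, experimentally varied
    g_GABA: 1.25
    g_AMPA_noise: 3.10
    g_AMPA_aff: 1.0     # uS, experimentally varied
    V_E: 0.0
    V_I: -70.0
    Mg: 1.0
    alpha_x: 1.0
    tau_x: 2.0
    alpha_s: 1.0
    tau_s_nmda: 80.0
    tau_s_gaba: 10.0
    tau_s_ampa: 2.0

interneuron:
  cell:
    Cm: 0.20
    gL_nS: 20.0
    V_L: -70.0
    V_th: -50.0
    V_rest: -60.0
    tau_ref: 2.0
  receptors:
    g_NMDA: 0.30        # uS, experimentally varied
    g_GABA: 1.0
    g_AMPA_noise: 2.38
    g_AMPA_aff: 0.0     # interneurons receive no stimulus afferent
    V_E: 0.0
    V_I: -70.0
    Mg: 1.0
    alpha_x: 1.0
    tau_x: 2.0
    alpha_s: 1.0
    tau_s_nmda: 80.0
    tau_s_gaba: 10.0
    tau_s_ampa: 2.0

drive:
  noise_rate_khz: 1.80      # background Poisson EPSP rate per neuron
  noise_weight: 0.001       # gating increment per noise event
  noise_to_interneurons: true
  aff_Fmax_khz: 1.25        # peak afferent Poisson rate
  aff_sigma: 0.4            # width of the afferent rate profile
  aff_weight: 0.001         # gating increment per afferent event

connectivity:
  n_pyr: 1024
  n_int: 256
  P: 0.7                    # localized proportion of pyr->pyr weight
  sigma_w: 0.05             # width of the localized weight profile
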