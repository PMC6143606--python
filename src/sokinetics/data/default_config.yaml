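# Reference configuration: fitted kinetic constants of the three-layer
# singlet-oxygen scheme for the two sulfonated aluminum phthalocyanines,
# plus the physical constants tying the model to the measurements.
physical_constants:
  alpha: 4.65e-19        # V m^2, adsorption potential per target density
  K_p: 4.4               # water/membrane oxygen partition coefficient
  P_M: 0.80              # m/s, membrane permeability to oxygen (80 cm/s)
  D_aq: 5.0e-9           # m^2/s, SO diffusion coefficient
  thickness: 4.0e-9      # m, membrane thickness
  tau_l_ref: 3.0e-6      # s, liposomal SO lifetime (travel-span reference)

rate_constants:
  AlPcS2:
    k_gen: 2.4           # m^2/s, SO generation per PS molecule
    k_so: 6.0e-10        # m^2/s, quenching by the S moiety
    k_to: 6.0e-10        # m^2/s, T-moiety oxidation (reported as a lower bound)
    k_ctm: 2.4e8         # 1/s, outer -> middle transfer (fixed from P_M)
    k_mct: 5.5e7         # 1/s, middle -> outer transfer (fixed from P_M)
    k_w: 5.0e7           # 1/s, loss from an outer layer
    k_w0: 2.9e7          # 1/s, quenching in the middle layer
    k_pso: 0.0           # m^2/s, PS self-quenching (neglected regime)
    k_ads: 0.0
    k_des: 5.0e-3        # 1/s, target desorption (dark-recovery timescale)
  AlPcS4:
    k_gen: 0.6
    k_so: 1.5e-10
    k_to: 6.0e-10
    k_ctm: 2.4e8
    k_mct: 5.5e7
    k_w: 5.0e7
    k_w0: 2.9e7
    k_pso: 0.0
    k_ads: 0.0
    k_des: 5.0e-3

fit:
  free_global: [k_w, k_w0, alpha_s0, k_to]
  free_local: [k_gen, k_so]
  fixed:
    k_ctm: 2.4e8
    k_mct: 5.5e7
    alpha: 4.65e-19
    k_pso: 0.0
  n_starts: 16
  weight_mode: on_inverse_rate
  n_boot: 0

synth:
  enabled: true
  alpha_s0_mV: 30.0      # invisible-target potential alpha*S_0
  noise_kind: none
  noise_scale: 0.0

experiment:
  side: cis
  ps_label: AlPcS2
  ps_density_per_um2: 228.0
  t0_mV: 20.0
  s0_mV: 30.0

seed: 0
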