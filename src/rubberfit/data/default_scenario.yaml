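# Shipped synthetic scenario: three conditions echoing the structure of
# common nitrogen-physiology experiment designs (an N-upshift time course,
# a low-ammonium steady state, and a GlnK-knockout steady state), all
# generated from an active-transporter ground truth.
seed: 12345
noise_cv: 0.03
true_params:
  vmax_amtb: 100.0   # mM/min
  km_amtb: 0.01      # mM
  p_diff: 50.0       # 1/min
  vmax_gs: 40.0      # mM/min
  km_gs: 0.1         # mM (GS-like affinity for ammonium)
  k_glnk: 0.02       # mM internal NH4+ at half-inhibition
  n_glnk: 2.0        # Hill coefficient (unsearched)
  mu_max: 0.4        # 1/min biomass nitrogen drain coefficient
  k_growth: 0.5      # mM glutamine half-saturation of growth
  k_dil: 10.0        # 1/min glutamine utilisation
class_assignment:
  vmax_amtb: I
  km_amtb: II
  p_diff: I
  vmax_gs: I
  km_gs: II
  k_glnk: II
  n_glnk: US
  mu_max: I
  k_growth: III
  k_dil: III
reference_dispersion:   # log-normal sigma of reference around truth
  I: 0.1
  II: 0.4
  III: 1.0
conditions:
  - condition_id: upshift
    physics: {mode: active, delta_psi_mV: -150.0, temperature_K: 310.0, ph_ext: 7.0, ph_int: 7.6}
    nhx_ext: 10.0
    pka: 9.25
    tau0: 52.0
    initial_state: {nhx_int: 0.02, gln: 0.4, glu: 40.0}
  - condition_id: lowN
    physics: {mode: active, delta_psi_mV: -150.0, temperature_K: 310.0, ph_ext: 7.0, ph_int: 7.6}
    nhx_ext: 0.05
    pka: 9.25
    tau0: 52.0
    initial_state: {nhx_int: 0.05, gln: 1.0, glu: 40.0}
  - condition_id: glnk_ko
    physics: {mode: active, delta_psi_mV: -150.0, temperature_K: 310.0, ph_ext: 7.0, ph_int: 7.6}
    nhx_ext: 1.0
    pka: 9.25
    tau0: 52.0
    initial_state: {nhx_int: 0.05, gln: 1.0, glu: 40.0}
    glnk_knockout: true
observation_plan:
  - {condition_id: upshift, variable: gln, kind: timecourse, times: [2, 5, 10, 20, 30], epsilon: 0.2}
  - {condition_id: upshift, variable: glu, kind: timecourse, times: [2, 5, 10, 20, 30], epsilon: 0.2}
  - {condition_id: upshift, variable: nhx_int, kind: timecourse, times: [2, 5, 10, 20, 30], epsilon: 0.2}
  - {condition_id: lowN, variable: growth_rate, kind: steady_state, epsilon: 0.1}
  - {condition_id: lowN, variable: v_net, kind: steady_state, epsilon: 0.2}
  - {condition_id: lowN, variable: nhx_int, kind: steady_state, epsilon: 0.2}
  - {condition_id: glnk_ko, variable: nhx_int, kind: steady_state, epsilon: 0.2}
  - {condition_id: glnk_ko, variable: v_amtb, kind: steady_state, epsilon: 0.2}
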