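# Synthetic parameterization of the CT -> GFAP glioma differentiation network.
#
# The published supplementary tables for this model (initial conditions and
# the 41 kinetic constants) are not redistributable here; the values below
# are a SYNTHETIC calibration of the same 10-state network structure
# (PKA/CREB, PI3K/AKT/pGSK3beta, IL6/JAK2/STAT3 branches, an ultrasensitive
# cyclin D1 positive-feedback switch, and cyclin-D1-repressed GFAP), tuned
# to reproduce the qualitative behaviour of the published model: an
# irreversible proliferation->differentiation switch, graded dose response
# over CT doses 0/5/7.5/10 ng/ml within 48 h, a GFAP differentiation
# threshold of 0.8, and strong noise sensitivity at intermediate doses.
#
# Concentrations are dimensionless (normalized to each species' dynamic
# range); time is in hours; CT dose in ng/ml.
schema: gliacap-model-parameters-v1
states:
  # name: initial condition (dimensionless normalized concentration)
  PKA: 0.0
  CREB: 0.0
  PI3K: 0.0
  AKT: 0.0
  pGSK3B: 0.0
  IL6: 0.0
  JAK2: 0.0
  STAT3: 0.0
  CCND1: 1.0
  GFAP: 0.05
drift_params:
  # --- PKA/CREB branch (CT -> PKA -> CREB) ---
  k_pka_act: 0.4        # /h, maximal CT-driven PKA activation rate
  K_ct_pka: 6.0         # ng/ml, CT half-saturation for PKA activation
  n_ct_pka: 2.0         # Hill coefficient, CT -> PKA
  k_pka_deact: 1.0      # /h, PKA deactivation
  k_creb_act: 1.0       # /h, PKA-driven CREB activation
  K_pka_creb: 1.0       # half-saturation of PKA effect on CREB
  k_creb_deact: 0.8     # /h, CREB deactivation
  # --- PI3K/AKT/pGSK3beta branch ---
  k_pi3k_act: 0.4       # /h, maximal CT-driven PI3K activation
  K_ct_pi3k: 5.0        # ng/ml
  n_ct_pi3k: 2.0        # Hill coefficient, CT -> PI3K
  k_pi3k_deact: 1.0     # /h
  k_akt_act: 1.0        # /h
  K_pi3k_akt: 1.0
  k_akt_deact: 0.8      # /h
  k_gsk_act: 1.0        # /h, AKT-driven GSK3beta phosphorylation
  K_akt_gsk: 1.0
  k_gsk_deact: 0.8      # /h
  # --- IL6/JAK2/STAT3 branch ---
  k_il6_act: 0.4        # /h, CT-driven IL6 induction
  K_ct_il6: 6.0         # ng/ml
  n_ct_il6: 2.0         # Hill coefficient, CT -> IL6
  k_il6_deact: 1.0      # /h
  k_jak_act: 1.0        # /h
  K_il6_jak: 1.0
  k_jak_deact: 0.8      # /h
  k_stat_act: 1.0       # /h
  K_jak_stat: 1.0
  k_stat_deact: 0.8     # /h
  # --- cyclin D1 switch ---
  k_ccnd1_basal: 0.02   # /h, basal cyclin D1 production
  k_ccnd1_fb: 0.5       # /h, maximal positive-feedback production
  K_ccnd1_fb: 0.5       # feedback half-saturation
  n_ccnd1_fb: 6.0       # Hill coefficient of the ultrasensitive feedback
  k_ccnd1_deg: 0.5      # /h, basal cyclin D1 turnover
  k_ccnd1_deg_ct: 10.0  # dimensionless, maximal CREB-driven degradation boost
  K_creb_deg: 3.0       # half-saturation of the CREB effect on degradation
  k_ccnd1_stab: 0.5     # dimensionless, pGSK3beta stabilization of cyclin D1
  # --- GFAP (differentiation marker) ---
  k_gfap_basal: 0.005   # /h, basal GFAP production
  k_gfap_creb: 0.8      # /h per unit CREB
  k_gfap_stat: 0.8      # /h per unit STAT3
  K_ccnd1_gfap: 0.3     # cyclin D1 level giving half-maximal GFAP repression
  n_ccnd1_gfap: 4.0     # Hill coefficient of cyclin D1 repression of GFAP
  k_gfap_deg: 0.06      # /h, GFAP turnover
noise_params:
  AN:
    sigma_add: 0.01     # default additive noise intensity (fraction of scale)
  CLE:
    sigma_int: 0.001    # intrinsic (reaction) noise std
    sigma_ext: 0.001    # extrinsic (cell-to-cell parameter) noise std
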