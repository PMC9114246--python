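# Bundled case study: whey-permeate lactic acid fermentation at three scales
# (laboratory 0.003 m³ working volume, pilot 0.1 m³, industrial 300 m³ vessel
# holding 207 m³). Impeller diameters are not stated by the source data and
# are anchored to the reported impeller Reynolds numbers at the nominal
# 3.333 s⁻¹ speed (see `reynolds_anchor`); the loader inverts Re = ρND²/μ.
# Provenance per numeric field: "reported" = printed source value,
# "derived" = back-computed here (oracle named).

cases:
  lab:
    fluid:
      density: 1060.0            # kg/m3, reported
      dynamic_viscosity: 0.0068  # Pa.s, reported
      kinematic_viscosity: 6.36e-6  # m2/s, reported (mu/rho = 6.415e-6; independently rounded)
      cell_size_range: [0.9, 1.9]   # um, reported
    vessel:
      total_volume: 0.03         # m3, reported vessel capacity
      working_volume: 0.003      # m3, reported
      actual_working_height: 0.18  # m, reported
      Z_over_T: 1.37             # reported
      H_over_T: 3.0              # reported
      D_over_T: 0.45             # reported (Reynolds back-derivation gives 0.449-0.451)
      target_Z_over_T: 1.37      # reference-scale aspect ratio
    impeller:
      type: RTB
      turbulent_power_number: 5.0
      # Chart-read effective Po at the transition-regime operating point
      # (Re = 1.81e3). Derived: bracketed jointly by the reported power
      # draw (0.257 W) and dissipation rate (0.080 W/kg), which pin
      # Po to 4.53-4.57; 4.55 adopted.
      effective_power_number: 4.55
      count: 2
      reynolds_anchor: {reynolds: 1.81e3, speed: 3.333}  # reported Re
    nominal_speed: 3.333         # 1/s, reported

  pilot:
    fluid:
      density: 1060.0
      dynamic_viscosity: 0.0057
      kinematic_viscosity: 5.37e-6  # reported (mu/rho = 5.377e-6)
      cell_size_range: [0.9, 1.9]
    vessel:
      total_volume: 0.1
      working_volume: 0.1
      actual_working_height: 0.65
      Z_over_T: 1.61
      H_over_T: 3.0
      D_over_T: 0.45
      target_Z_over_T: 1.32
    impeller:
      type: RTB
      turbulent_power_number: 5.0
      count: 2
      reynolds_anchor: {reynolds: 2.040e4, speed: 3.333}
    nominal_speed: 3.333

  industrial:
    fluid:
      density: 1060.0
      dynamic_viscosity: 0.0057
      kinematic_viscosity: 5.37e-6
      cell_size_range: [0.9, 1.9]
    vessel:
      total_volume: 300.0
      working_volume: 207.0
      actual_working_height: 11.47
      Z_over_T: 2.55
      H_over_T: 3.0
      D_over_T: 0.45
      target_Z_over_T: 1.33
      # Alternative working height: the pilot similarity ratio (0.81, the
      # pilot Z_calc/Z0 at reporting precision) projected onto 11.47 m
      # gives Z = 9.29 m, restoring acceptable vessel occupancy.
      alt_similarity_ratio: 0.81
    impeller:
      type: RTB
      turbulent_power_number: 5.0
      count: 2
      reynolds_anchor: {reynolds: 2.553190e6, speed: 3.333}
    nominal_speed: 3.333
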