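# Shipped default configuration: initial token levels (relative activity
# units) and per-transition rate constants for the three pathway variants.
# All arc weights are 1; the only non-unit structural number is the
# metformin inhibitory-arc weight below (gate half-point), a calibration
# choice.  Rate constants marked "calibrated" were tuned once, jointly, so
# the default models reproduce the reference fold-change bounds; everything
# else is the neutral default 1 or a round timescale choice.

variants:
  normal_adipocyte:
    places: &base_places
      insulin: 0.0
      insulin_receptor: 1.0
      complex1: 0.0
      irs1_inactive: 1.0
      irs1_active: 0.05
      pi3k_inactive: 1.0
      pi3k_active: 0.05
      pip3: 0.05
      pdk1: 1.0
      mtorc2: 1.0
      akt_inactive: 1.0
      akt_active: 0.05
      glut4_internal: 1.0
      glut4_membrane: 0.05
      cell_survival: 0.01
      glucose: 1.0
      udp_glcnac: 0.02
      ogt_mrna: 0.5
      ogt: 0.02
      oga: 1.0
    rates: &base_rates
      src_insulin: 0.5
      dec_insulin: 0.5
      bind_receptor: 0.5
      dec_complex1: 0.5
      act_irs1: 1.0
      deact_irs1: 1.0
      oglcnac_irs1: 0.2        # balanced cycling in the normal cell
      deglcnac_irs1: 0.02
      act_pi3k: 1.0
      deact_pi3k: 1.0
      syn_pip3: 1.0
      dec_pip3: 1.0
      act_akt: 0.34            # calibrated: sets the normal Akt operating point
      deact_akt: 1.0
      oglcnac_akt: 0.2         # balanced cycling in the normal cell
      deglcnac_akt: 0.02
      translocate_glut4: 1.0
      internalize_glut4: 1.0
      proliferate: 1.0
      dec_survival: 0.5
      src_glucose: 0.5
      dec_glucose: 0.5
      hbp_flux: 0.02           # ~4% of glucose turnover routed to the HBP
      dec_udp: 1.0
      transcribe_ogt: 0.05
      dec_ogt_mrna: 0.1
      syn_ogt: 0.2
      dec_ogt: 0.1

  insulin_resistant_adipocyte:
    places: *base_places
    rates:
      <<: *base_rates
      transcribe_ogt: 0.42     # calibrated: ~5x OGT elevation, matching the
                               # hyperglycemic cancer cell's elevation
      oglcnac_irs1: 10.0       # calibrated: elevated OGT-driven IRS-1 deactivation
      oglcnac_akt: 20.0        # calibrated: elevated OGT-driven Akt deactivation

  cancer_hyperglycemia:
    places:
      <<: *base_places
      glucose: 5.0             # hyperglycemia: elevated initial glucose
    rates:
      <<: *base_rates
      src_glucose: 2.5         # hyperglycemia: 5x glucose supply
      translocate_glut4: 12.0  # calibrated: OGT-boosted GLUT4 surface delivery
      proliferate: 25.0        # calibrated: OGT-boosted proliferation drive
      ogt_boost_akt: 40.0      # calibrated: OGT-driven Akt hyper-activation
      oga_damp_akt: 0.1

interventions:
  doses:                       # default initial tokens of the drug/RNA places
    shrna: 10.0
    bzx: 10.0
    metformin: 10.0
  rates:
    degrade_ogt_mrna: 0.3     # calibrated: shRNA-guided OGT mRNA degradation
    sequester_ogt: 0.1        # calibrated: covalent BZX-OGT complex formation
    metformin_upkeep_per_dose: 0.001   # slow replenishment of the drug pool
  metformin_gate_weight: 7.0  # inhibitory-arc weight: half-suppression point
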