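# 63 MeV cyclotron irradiation of a thin (1 cm) + thick (23 cm) PMMA target
# pair separated by a 3 cm air gap, viewed by one Cherenkov module at 90
# degrees / 14 cm facing the Bragg-peak region.  Range shifts are emulated by
# widening the air gap.
name: medicyc_63mev
beam_energy_mev: 63.0

accelerator:
  bunch_period_ns: 40.0
  bunch_width_ns: 4.0

delivery:
  mean_protons_per_bunch: 0.025
  monitor_coverage: 1.0        # collimated beam: the monitor sees everything

geometry:
  slabs:
    - {material: PMMA, thickness_cm: 1.0}
    - {material: air,  thickness_cm: 3.0}
    - {material: PMMA, thickness_cm: 23.0}
  gap_index: 1

monitor:
  time_resolution_fwhm_ps: 156.0

detectors:
  - id: module90
    angle_deg: 90.0
    distance_cm: 14.0
    anchor: bragg_peak
    face_area_cm2: 1.0
    # module resolution chosen so that the quadrature sum with the 156 ps
    # monitor gives the 315 ps FWHM system coincidence time resolution
    time_resolution_fwhm_ps: 273.7
    threshold_pe: 6
    dark_count_rate_hz: 302.0

backgrounds:
  coincidence_window_ns: 20.0

analysis:
  time_bin_ps: 50.0
  space_bin_cm: 0.5
  bootstrap:
    n_toys: 5000
    subsample_sizes: [30, 45, 60, 75, 90, 105, 120, 135]
    target_n: 600

seed: 0
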