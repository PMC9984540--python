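# 148 MeV synchro-cyclotron irradiation of a thick (23 cm) PMMA target that
# stops the beam after 13.4 cm, viewed by two identical Cherenkov modules:
# one upstream (157 degrees) and one above the Bragg peak (90 degrees).
# The uncollimated monitor covers only ~20% of the beam, so untagged protons
# produce a bunch-structured random-coincidence background.
name: s2c2_148mev
beam_energy_mev: 148.0

accelerator:
  bunch_period_ns: 16.0
  bunch_width_ns: 8.0
  pulse_width_us: 8.0
  pulse_period_ms: 1.0

delivery:
  mean_protons_per_bunch: 0.78
  monitor_coverage: 0.2

geometry:
  slabs:
    - {material: PMMA, thickness_cm: 23.0}
  gap_index: null

monitor:
  time_resolution_fwhm_ps: 360.0

detectors:
  - id: detA
    angle_deg: 157.0
    distance_cm: 15.0
    anchor: bragg_peak
    face_area_cm2: 2.0
    time_resolution_fwhm_ps: 167.0
    threshold_pe: 9
    dark_count_rate_hz: 0.0   # high threshold: dark counts negligible
  - id: detB
    angle_deg: 90.0
    distance_cm: 15.0
    anchor: bragg_peak
    face_area_cm2: 2.0
    time_resolution_fwhm_ps: 167.0
    threshold_pe: 9
    dark_count_rate_hz: 0.0

backgrounds:
  coincidence_window_ns: 15.0
  random_coincidence_rate_hz: 5.0
  bunch_sigma_ns: 1.27     # measured micro-bunch sigma

analysis:
  time_bin_ps: 50.0
  space_bin_cm: 0.5
  bootstrap:
    n_toys: 5000
    subsample_sizes: [30, 45, 60, 75, 90, 105, 120, 135]
    target_n: 600

seed: 0
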