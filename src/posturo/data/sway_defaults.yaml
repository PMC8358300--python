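conditions:
  1:
    cutoff_ap_hz: 1.4375
    cutoff_ml_hz: 2.328125
    rms_ap_mm: 4.649795
    rms_ml_mm: 1.666908
  2:
    cutoff_ap_hz: 1.5
    cutoff_ml_hz: 2.171875
    rms_ap_mm: 5.22632
    rms_ml_mm: 2.017836
  3:
    cutoff_ap_hz: 1.5
    cutoff_ml_hz: 2.15625
    rms_ap_mm: 4.887925
    rms_ml_mm: 2.168233
  4:
    cutoff_ap_hz: 1.609375
    cutoff_ml_hz: 1.5
    rms_ap_mm: 6.893228
    rms_ml_mm: 3.94794
  5:
    cutoff_ap_hz: 1.65625
    cutoff_ml_hz: 1.5
    rms_ap_mm: 7.41962
    rms_ml_mm: 4.060738
  6:
    cutoff_ap_hz: 1.53125
    cutoff_ml_hz: 1.421875
    rms_ap_mm: 7.41962
    rms_ml_mm: 3.91034
filter_order: 4
sampling_rate: 200.0
tau: 0.25
trial_duration: 20.0
trial_noise: 0.1
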