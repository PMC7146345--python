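# Default movement-class table for the synthetic IMU generator.
#
# The nine movements form a graded intensity ladder (amplitude ratio ~1.6
# between adjacent rungs, from a 0.85 m/s^2 walking arm sway to a ~4 g
# badminton smash): walking gentlest, pick-ups slow and small, services
# moderate, strokes/spins faster, the smash most energetic.  Because the
# sensor noise of every class is defined as 20% of its own amplitude,
# between-class gaps are what make the classes distinguishable at all;
# three further choices keep all four magnitude streams (acceleration,
# velocity, displacement, angle) separable under that noise and +-10%
# subject scaling:
#   * oscillation frequencies sit in a narrow 5-7.3 Hz band (sub-movement
#     vibration faster than the 0.2 s analysis window, so windowed maxima
#     read the envelope, not the phase);
#   * the nominal wrist-attitude tilt grows with the square root of amplitude
#     (80 deg x sqrt(A/39.5)), keeping angle-stream gaps scale-matched to the
#     amplitude-proportional noise;
#   * gyroscope amplitude grows as 60*sqrt(A), limiting integration drift
#     of the fused angles for the vigorous classes.
# Biomechanical fidelity is out of scope; these are periodic,
# class-distinct surrogates.
classes:
- class_id: 0
  name: walking
  accel_amplitude: [0.47, 0.3, 0.85]
  gyro_amplitude: [30.4, 19.4, 55.3]
  base_frequency: 5.0
  phase_offsets: [0.0, 1.0, 2.0]
  noise_sigma_accel: 0.17
  noise_sigma_gyro: 11.1
  gravity_direction: [0.0, 0.0, 1.0]
- class_id: 1
  name: tt_service
  accel_amplitude: [3.6, 1.98, 1.26]
  gyro_amplitude: [113.8, 62.6, 39.8]
  base_frequency: 5.8
  phase_offsets: [0.0, 0.8, 1.6]
  noise_sigma_accel: 0.72
  noise_sigma_gyro: 22.8
  gravity_direction: [0.0, 0.40915, 0.912467]
- class_id: 2
  name: tt_stroke
  accel_amplitude: [9.4, 5.17, 3.29]
  gyro_amplitude: [184.0, 101.2, 64.4]
  base_frequency: 6.4
  phase_offsets: [0.5, 1.3, 2.1]
  noise_sigma_accel: 1.88
  noise_sigma_gyro: 36.8
  gravity_direction: [0.0, 0.629675, 0.776859]
- class_id: 3
  name: tt_spin
  accel_amplitude: [15.0, 8.25, 5.25]
  gyro_amplitude: [232.4, 127.8, 81.3]
  base_frequency: 6.7
  phase_offsets: [1.0, 1.8, 2.6]
  noise_sigma_accel: 3.0
  noise_sigma_gyro: 46.5
  gravity_direction: [0.758122, 0.0, 0.652113]
- class_id: 4
  name: tt_pickup
  accel_amplitude: [0.77, 0.49, 1.4]
  gyro_amplitude: [39.0, 24.8, 71.0]
  base_frequency: 5.2
  phase_offsets: [0.3, 1.1, 1.9]
  noise_sigma_accel: 0.28
  noise_sigma_gyro: 14.2
  gravity_direction: [0.0, 0.259848, 0.965649]
- class_id: 5
  name: bd_service
  accel_amplitude: [5.8, 3.19, 2.03]
  gyro_amplitude: [144.5, 79.5, 50.6]
  base_frequency: 6.1
  phase_offsets: [0.7, 1.5, 2.3]
  noise_sigma_accel: 1.16
  noise_sigma_gyro: 28.9
  gravity_direction: [0.509872, 0.0, 0.86025]
- class_id: 6
  name: bd_drive
  accel_amplitude: [24.5, 13.48, 8.57]
  gyro_amplitude: [297.0, 163.3, 103.9]
  base_frequency: 7.0
  phase_offsets: [0.2, 1.0, 1.8]
  noise_sigma_accel: 4.9
  noise_sigma_gyro: 59.4
  gravity_direction: [0.0, 0.891046, 0.453914]
- class_id: 7
  name: bd_smash
  accel_amplitude: [39.5, 21.73, 13.82]
  gyro_amplitude: [377.1, 207.4, 132.0]
  base_frequency: 7.3
  phase_offsets: [0.9, 1.7, 2.5]
  noise_sigma_accel: 7.9
  noise_sigma_gyro: 75.4
  gravity_direction: [0.984808, 0.0, 0.173648]
- class_id: 8
  name: bd_pickup
  accel_amplitude: [1.21, 0.77, 2.2]
  gyro_amplitude: [48.9, 31.1, 89.0]
  base_frequency: 5.5
  phase_offsets: [0.4, 1.2, 2.0]
  noise_sigma_accel: 0.44
  noise_sigma_gyro: 17.8
  gravity_direction: [0.323588, 0.0, 0.946198]
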