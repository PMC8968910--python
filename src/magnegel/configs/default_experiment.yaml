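# Default end-to-end experiment: calibrated two-magnet device, particle
# tracing with 250 nm MNPs, and a synthetic dose series of gel images.
seed: 1
output_dir: magnegel_out

device:
  face_length_mm: 40.0
  face_width_mm: 20.0
  depth_mm: 10.0
  gap_mm: 7.2
  remanence_T: 1.31
  calibration_target_mT: 52.3

simulation:
  n_particles: 2000
  dt: 0.01
  t_end: 0.1
  droplet_volume: 1.0e-7   # m^3 = 100 µl
  brownian: false

groups:
  - name: dose_0.00
    n_images: 3
    n_gaps: 0
    scene: {kind: segmented_gel, size: [256, 384], pixel_size_um: 1.61}
  - name: dose_0.25
    n_images: 3
    n_gaps: 2
    scene: {kind: segmented_gel, size: [256, 384], pixel_size_um: 1.61}
  - name: dose_0.50
    n_images: 3
    n_gaps: 4
    scene: {kind: segmented_gel, size: [256, 384], pixel_size_um: 1.61}
  - name: dose_0.75
    n_images: 3
    n_gaps: 6
    scene: {kind: segmented_gel, size: [256, 384], pixel_size_um: 1.61}
  - name: dose_1.00
    n_images: 3
    n_gaps: 8
    scene: {kind: segmented_gel, size: [256, 384], pixel_size_um: 1.61}
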