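# Terminal (impinging-flow) ICA-like aneurysm, desk-scale grid.
# All lengths in meters.
geometry:
  parent_radius: 2.0e-3
  parent_length: 16.0e-3
  dome_radius: 3.0e-3
  neck_width: 3.0e-3
  dome_offset_angle: 1.5707963267948966   # pi/2: dome in line with the inflow jet
  inlet_extension: 4.0e-3
coil:
  mode: RM_rough
  roughness_amplitude: 0.15
  roughness_correlation_length: 1.0e-3
  seed: 0
grid_spacing: 0.5e-3
seed: 1
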