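# Homogeneous-PMMA reference run: 220 MeV/u carbon into a PMMA block,
# planar tracker at 90 degrees aimed at the emission region.
seed: 42
beam:
  particle: 12C
  E_u: 220.0
  entry_point: [0.0, 0.0, -8.0]
  direction: [0.0, 0.0, 1.0]
  sigma_beam: 0.4
phantom:
  regions:
    - solid: {type: box, center: [0.0, 0.0, 1.35], size: [12.0, 12.0, 15.0]}
      material: pmma
tracker:
  theta: 90.0
  distance: 40.0
  a: 20.0
  b: 20.0
  angular_sigma: 0.004
  point_sigma: 0.02
  reference: [0.0, 0.0, -1.7]
emission:
  cone_half_angle: 0.12
analysis:
  n_tracks: 20000
  bin_width: 0.2
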