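# Sphere-in-sphere absorption-unfolding run: a 10-cm PMMA sphere
# (1.2 g/cm^3) with a 3-cm low-density insert.  The exit-path thickness
# varies strongly with emission depth, so the run enables LUT unfolding.
# The LUT span reaches 13 cm because the deepest emission points see up to
# ~12 cm of water-equivalent material toward the tracker; "clip" handles the
# thin sliver below the first node.
seed: 11
beam:
  particle: 12C
  E_u: 220.0
  entry_point: [0.0, 0.0, -12.0]
  direction: [0.0, 0.0, 1.0]
  sigma_beam: 0.4
phantom:
  regions:
    - solid: {type: sphere, center: [0.0, 0.0, 0.0], radius: 10.0}
      material: pmma
      density: 1.2
    - solid: {type: sphere, center: [0.0, 0.0, 0.0], radius: 3.0}
      material: pmma
      density: 0.6
tracker:
  theta: 90.0
  distance: 40.0
  angular_sigma: 0.004
  point_sigma: 0.02
  reference: [0.0, 0.0, -5.5]
emission:
  cone_half_angle: 0.12
analysis:
  n_tracks: 20000
  bin_width: 0.2
unfolding:
  enabled: true
  thicknesses: [2.5, 4.0, 5.5, 7.0, 8.5, 10.0, 11.5, 13.0]
  n_tracks: 15000
  mode: clip
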