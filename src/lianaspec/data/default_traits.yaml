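# Default synthetic trait distributions per growth form.
#
# Each trait: [mean, sd, lower bound, upper bound] of a truncated normal.
# The liana/tree contrasts encode the field pattern: lianas build cheaper
# leaves (thinner; lower chlorophyll, carotenoid, dry-mass and water content
# per unit area; relative differences of ~15-25%) and hold them flatter
# (mean inclination 27.9 vs 37.1 degrees from zenith, i.e. 24.8% flatter).
# Adapt the means/sds to match any particular site.
#
# Units: n_layers unitless (>= 1); c_ab, c_ar, c_an ug/cm^2; c_br arbitrary;
# c_w, c_m g/cm^2; omega degrees from zenith.
tree:
  n_layers: [1.80, 0.25, 1.0, 3.0]
  c_ab:     [45.0, 10.0, 5.0, 100.0]
  c_ar:     [10.0, 2.0,  0.5, 30.0]
  c_an:     [1.0,  0.5,  0.0, 10.0]
  c_br:     [0.15, 0.10, 0.0, 1.0]
  c_w:      [0.012, 0.0030, 0.002, 0.05]
  c_m:      [0.010, 0.0025, 0.002, 0.03]
  omega:    [37.1, 10.0, 5.0, 85.0]
liana:
  n_layers: [1.55, 0.22, 1.0, 3.0]
  c_ab:     [35.0, 9.0,  5.0, 100.0]
  c_ar:     [8.0,  1.8,  0.5, 30.0]
  c_an:     [1.0,  0.5,  0.0, 10.0]
  c_br:     [0.15, 0.10, 0.0, 1.0]
  c_w:      [0.009, 0.0025, 0.002, 0.05]
  c_m:      [0.0075, 0.0020, 0.002, 0.03]
  omega:    [27.9, 10.0, 5.0, 85.0]
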