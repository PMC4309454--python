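# Three-chromosome miniature preset: quick end-to-end demonstration.
preset: small
n_lines: 40
n_markers: 60
generations: 11
missing_rate: 0.0
error_rate: 0.0
depth:
  mean: 6
  fixed: true
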