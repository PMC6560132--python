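# Ballesteros-Weinstein X.50 anchors for hTAS2R16, consistent with the
# published helix superscripts (L59=2.53, E86=3.33, N89=3.36, Q177=5.39,
# H181=5.43, F236=6.48, E262=7.39, Y266=7.43).
- tm: 2
  anchor: 56
  range: [48, 75]
- tm: 3
  anchor: 103
  range: [78, 110]
- tm: 5
  anchor: 188
  range: [170, 200]
- tm: 6
  anchor: 238
  range: [225, 255]
- tm: 7
  anchor: 273
  range: [256, 285]
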