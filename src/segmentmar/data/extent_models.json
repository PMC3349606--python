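{
  "_comment": "Default normal/maximal perfusion-territory extent models per culprit artery, on the extended AHA bulls-eye (9 rings base->apex x 24 sectors counterclockwise from the inferior RV insertion point). Each ring is given as [start_sector, arc_length]; arcs wrap circularly. These are a parametric consensus-style reading of typical coronary territories and are replaceable by user files. LM is assembled as the union of LAD, LCx and RCA.",
  "LAD": {
    "maximal": [[10, 13], [10, 13], [10, 13], [9, 15], [9, 15], [9, 15], [8, 16], [8, 16], [0, 24]],
    "normal":  [[12, 8], [12, 8], [12, 8], [11, 10], [11, 10], [11, 10], [10, 12], [10, 12], [4, 16]]
  },
  "LCx": {
    "maximal": [[4, 10], [4, 10], [4, 10], [4, 10], [4, 10], [4, 10], [5, 8], [5, 8], [5, 8]],
    "normal":  [[6, 6], [6, 6], [6, 6], [6, 6], [6, 6], [6, 6], [6, 5], [6, 5], [6, 5]]
  },
  "RCA": {
    "maximal": [[20, 10], [20, 10], [20, 10], [20, 10], [20, 10], [20, 10], [21, 8], [21, 8], [21, 8]],
    "normal":  [[22, 6], [22, 6], [22, 6], [22, 6], [22, 6], [22, 6], [23, 4], [23, 4], [23, 4]]
  }
}
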