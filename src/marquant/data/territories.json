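{
  "_comment": "Maximal-extent perfusion territories over 24 circumferential sectors (index 0 at the anterior RV insertion, counterclockwise: anterior -> anterolateral -> inferolateral -> inferior -> inferoseptal -> anteroseptal). Derived from the standard AHA 17-segment artery assignment, dilated by one 15-degree sector on each circumferential edge to represent the maximal extent of a proximal occlusion. Replaceable by the user. LM is computed as the union of LAD and LCx.",
  "LAD": {
    "basal":  [19, 20, 21, 22, 23, 0, 1, 2, 3, 4],
    "mid":    [19, 20, 21, 22, 23, 0, 1, 2, 3, 4],
    "apical": [18, 19, 20, 21, 22, 23, 0, 1, 2, 3, 4, 5]
  },
  "LCx": {
    "basal":  [3, 4, 5, 6, 7, 8, 9, 10, 11, 12],
    "mid":    [3, 4, 5, 6, 7, 8, 9, 10, 11, 12],
    "apical": [3, 4, 5, 6, 7, 8, 9, 10, 11, 12]
  },
  "RCA": {
    "basal":  [11, 12, 13, 14, 15, 16, 17, 18, 19, 20],
    "mid":    [11, 12, 13, 14, 15, 16, 17, 18, 19, 20],
    "apical": [11, 12, 13, 14, 15, 16, 17, 18, 19, 20]
  }
}
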