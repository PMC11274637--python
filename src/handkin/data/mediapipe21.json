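{
  "name": "mediapipe21",
  "n_landmarks": 21,
  "joint_triples": {
    "thumb": [
      2,
      3,
      4
    ],
    "index": [
      5,
      6,
      7
    ],
    "middle": [
      9,
      10,
      11
    ],
    "ring": [
      13,
      14,
      15
    ],
    "pinky": [
      17,
      18,
      19
    ]
  },
  "rom_cap_deg": 180.0,
  "native_fps": 30.0,
  "landmark_names": [
    "wrist",
    "thumb_cmc",
    "thumb_mcp",
    "thumb_ip",
    "thumb_tip",
    "index_mcp",
    "index_pip",
    "index_dip",
    "index_tip",
    "middle_mcp",
    "middle_pip",
    "middle_dip",
    "middle_tip",
    "ring_mcp",
    "ring_pip",
    "ring_dip",
    "ring_tip",
    "pinky_mcp",
    "pinky_pip",
    "pinky_dip",
    "pinky_tip"
  ]
}
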