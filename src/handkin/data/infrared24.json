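{
  "name": "infrared24",
  "n_landmarks": 24,
  "joint_triples": {
    "thumb": [
      4,
      5,
      6
    ],
    "index": [
      8,
      9,
      10
    ],
    "middle": [
      12,
      13,
      14
    ],
    "ring": [
      16,
      17,
      18
    ],
    "pinky": [
      20,
      21,
      22
    ]
  },
  "rom_cap_deg": 90.0,
  "native_fps": 60.0,
  "landmark_names": [
    "elbow",
    "forearm",
    "wrist",
    "palm",
    "thumb_mcp",
    "thumb_pip",
    "thumb_dip",
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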