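{
  "canonical_width": 1800,
  "canonical_height": 1200,
  "y_anchors": [
    [
      0.0,
      1150.0
    ],
    [
      40.0,
      510.0
    ],
    [
      80.0,
      190.0
    ]
  ],
  "day_origin_x": 170.0,
  "day_width": 260.0,
  "slot_offsets_px": [
    0.0,
    68.0,
    120.0,
    188.0,
    240.0
  ],
  "days": 6,
  "header_region": [
    40,
    20,
    560,
    140
  ],
  "date_region": [
    620,
    30,
    1060,
    130
  ]
}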