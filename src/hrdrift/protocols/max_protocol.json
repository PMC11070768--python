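{
  "protocol": "MAX",
  "offset_label": "A",
  "end_label": "E",
  "points": {
    "A": {"segment_label": "rest", "occurrence": 0, "origin": "end", "offset_s": -60, "duration_s": 60},
    "B": {"segment_label": "walk", "occurrence": 0, "origin": "start", "offset_s": 30, "duration_s": null},
    "C": {"segment_label": "run", "occurrence": 0, "origin": "start", "offset_s": 120, "duration_s": 60},
    "D": {"segment_label": "run", "occurrence": 0, "origin": "mid", "offset_s": -30, "duration_s": 60},
    "E": {"segment_label": "run", "occurrence": 0, "origin": "end", "offset_s": -30, "duration_s": 30},
    "F": {"segment_label": "rest", "occurrence": 2, "origin": "start", "offset_s": 1200, "duration_s": 60}
  },
  "drift_delta": {"pre": "A", "post": "F"}
}
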