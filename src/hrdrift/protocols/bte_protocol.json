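{
  "protocol": "BTE",
  "offset_label": "A",
  "end_label": "D",
  "points": {
    "A": {"segment_label": "walk", "occurrence": 0, "origin": "start", "offset_s": 30, "duration_s": null},
    "B": {"segment_label": "run", "occurrence": 0, "origin": "start", "offset_s": 480, "duration_s": 120},
    "C": {"segment_label": "run", "occurrence": 0, "origin": "start", "offset_s": 1200, "duration_s": 120},
    "D": {"segment_label": "run", "occurrence": 0, "origin": "end", "offset_s": -150, "duration_s": 120},
    "E": {"segment_label": "walk", "occurrence": 1, "origin": "start", "offset_s": 30, "duration_s": null, "end_trim_s": 30},
    "F": {"segment_label": "walk", "occurrence": 2, "origin": "start", "offset_s": 30, "duration_s": null, "end_trim_s": 30}
  },
  "drift_delta": {"pre": "A", "post": "E"}
}
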