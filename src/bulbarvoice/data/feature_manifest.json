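{
  "version": "1.0",
  "description": "Versioned manifest of the 53 acoustic features: name -> category, in canonical column order. Categories: jitter (5), shimmer (6), harmonicity (5), f0 (7), intensity (7), zcr (2), timing_rate (21).",
  "features": [
    {"name": "jitter_local", "category": "jitter", "unit": "%"},
    {"name": "jitter_local_abs", "category": "jitter", "unit": "s"},
    {"name": "jitter_rap", "category": "jitter", "unit": "%"},
    {"name": "jitter_ppq5", "category": "jitter", "unit": "%"},
    {"name": "jitter_ddp", "category": "jitter", "unit": "%"},
    {"name": "shimmer_local", "category": "shimmer", "unit": "%"},
    {"name": "shimmer_local_db", "category": "shimmer", "unit": "dB"},
    {"name": "shimmer_apq3", "category": "shimmer", "unit": "%"},
    {"name": "shimmer_apq5", "category": "shimmer", "unit": "%"},
    {"name": "shimmer_apq11", "category": "shimmer", "unit": "%"},
    {"name": "shimmer_dda", "category": "shimmer", "unit": "%"},
    {"name": "hnr_mean", "category": "harmonicity", "unit": "dB"},
    {"name": "hnr_sd", "category": "harmonicity", "unit": "dB"},
    {"name": "ac_mean", "category": "harmonicity", "unit": ""},
    {"name": "cc_mean", "category": "harmonicity", "unit": ""},
    {"name": "nhr_mean", "category": "harmonicity", "unit": ""},
    {"name": "f0_mean", "category": "f0", "unit": "Hz"},
    {"name": "f0_median", "category": "f0", "unit": "Hz"},
    {"name": "f0_min", "category": "f0", "unit": "Hz"},
    {"name": "f0_max", "category": "f0", "unit": "Hz"},
    {"name": "f0_range", "category": "f0", "unit": "Hz"},
    {"name": "f0_var", "category": "f0", "unit": "Hz^2"},
    {"name": "f0_sd", "category": "f0", "unit": "Hz"},
    {"name": "int_mean", "category": "intensity", "unit": "dB"},
    {"name": "int_median", "category": "intensity", "unit": "dB"},
    {"name": "int_min", "category": "intensity", "unit": "dB"},
    {"name": "int_max", "category": "intensity", "unit": "dB"},
    {"name": "int_range", "category": "intensity", "unit": "dB"},
    {"name": "int_var", "category": "intensity", "unit": "dB^2"},
    {"name": "int_sd", "category": "intensity", "unit": "dB"},
    {"name": "zcr_mean", "category": "zcr", "unit": "per-sample fraction"},
    {"name": "zcr_var", "category": "zcr", "unit": ""},
    {"name": "total_dur", "category": "timing_rate", "unit": "s"},
    {"name": "speech_dur_total", "category": "timing_rate", "unit": "s"},
    {"name": "pause_dur_total", "category": "timing_rate", "unit": "s"},
    {"name": "pause_ct", "category": "timing_rate", "unit": "count"},
    {"name": "pause_ct_short", "category": "timing_rate", "unit": "count"},
    {"name": "pause_ct_med", "category": "timing_rate", "unit": "count"},
    {"name": "pause_ct_long", "category": "timing_rate", "unit": "count"},
    {"name": "pause_dur_mean", "category": "timing_rate", "unit": "s"},
    {"name": "pause_dur_median", "category": "timing_rate", "unit": "s"},
    {"name": "pause_dur_var", "category": "timing_rate", "unit": "s^2"},
    {"name": "pause_dur_max", "category": "timing_rate", "unit": "s"},
    {"name": "pause_rate", "category": "timing_rate", "unit": "1/s"},
    {"name": "speech_seg_ct", "category": "timing_rate", "unit": "count"},
    {"name": "speech_seg_dur_median", "category": "timing_rate", "unit": "s"},
    {"name": "speech_seg_dur_max", "category": "timing_rate", "unit": "s"},
    {"name": "phonation_ratio", "category": "timing_rate", "unit": ""},
    {"name": "speech_rate", "category": "timing_rate", "unit": "syll/s"},
    {"name": "articulation_rate", "category": "timing_rate", "unit": "syll/s"},
    {"name": "syllable_ct", "category": "timing_rate", "unit": "count"},
    {"name": "word_dur_mean", "category": "timing_rate", "unit": "s"},
    {"name": "word_dur_var", "category": "timing_rate", "unit": "s^2"}
  ],
  "interaction_subsets": {
    "f0": ["f0_mean", "f0_median", "f0_min", "f0_max", "f0_range", "f0_var", "f0_sd"],
    "hnr": ["hnr_mean", "hnr_sd"]
  }
}
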