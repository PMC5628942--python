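{
  "total_tweets": {
    "SH": 1815751,
    "BB": 1147793,
    "SF": 430616,
    "NE": 205073,
    "MV": 249847
  },
  "peak_tpm_first_60": {
    "BB": 3326,
    "SF": 1423,
    "MV": 957,
    "NE": 739,
    "SH": 209
  },
  "threshold_200_fire_minute": {
    "NE": 2,
    "BB": 7,
    "SF": 18
  }
}
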