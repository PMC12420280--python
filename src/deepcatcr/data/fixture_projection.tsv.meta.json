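{
 "explained_variance_ratio": [
  NaN,
  NaN,
  NaN,
  NaN,
  NaN,
  NaN,
  NaN,
  NaN,
  NaN,
  NaN,
  NaN,
  NaN,
  NaN,
  NaN,
  NaN
 ],
 "cumulative_variance": NaN,
 "n_source_indices": 0
}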