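{
 "explained_variance_ratio": [
  0.314034126359615,
  0.23109436777401285,
  0.1273802787382803,
  0.11097836348334755,
  0.08937332537095392,
  0.0636934198910269,
  0.03804426139871256,
  0.008648532912618037,
  0.0019723205055389866,
  0.001863272113239459,
  0.001703220335453872,
  0.001673704715143045,
  0.0015811476012775408,
  0.0015387128952573626,
  0.001457189926553447
 ],
 "cumulative_variance": 0.9950362440210309,
 "n_source_indices": 553
}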