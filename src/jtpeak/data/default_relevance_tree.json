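{
 "metadata": {
  "features": [
   "slur_slope_angle",
   "peak_slur_angle",
   "peak_slur_origin_ratio"
  ],
  "max_depth": 4,
  "seed": 7,
  "n_examples": 500,
  "version": 1,
  "training_set_id": "synthetic-slur-corpus-n500-seed7"
 },
 "root": {
  "feature": "slur_slope_angle",
  "threshold": 4.183056473731995,
  "left": {
   "label": "irrelevant"
  },
  "right": {
   "label": "relevant"
  }
 }
}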