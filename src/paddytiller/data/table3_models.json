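{
 "F1": {
  "feature_names": [
   "total_area"
  ],
  "coefficients": [
   0.0045
  ],
  "intercept": 3.5401,
  "form": "y = 0.0045*x + 3.5401"
 },
 "F2": {
  "feature_names": [
   "hull_area"
  ],
  "coefficients": [
   0.002953598960333166
  ],
  "intercept": 2.7799864134447825,
  "form": "y = (x + 941.22) / 338.57"
 },
 "F3": {
  "feature_names": [
   "perimeter"
  ],
  "coefficients": [
   0.03035638394754417
  ],
  "intercept": 0.18472770323599053,
  "form": "y = (x + 6.0853) / 32.942"
 },
 "F4": {
  "feature_names": [
   "rect_width"
  ],
  "coefficients": [
   0.17627668388302278
  ],
  "intercept": -1.4950730666854695,
  "form": "y = (x - 8.4814) / 5.6729"
 },
 "F5": {
  "feature_names": [
   "rect_height"
  ],
  "coefficients": [
   0.24676125848241826
  ],
  "intercept": -3.6449105490438,
  "form": "y = (x - 14.771) / 4.0525"
 },
 "F6": {
  "feature_names": [
   "green_value"
  ],
  "coefficients": [
   1.1325028312570782
  ],
  "intercept": -12.652321630804078,
  "form": "y = (x - 11.172) / 0.883"
 },
 "MF1": {
  "feature_names": [
   "total_area",
   "perimeter"
  ],
  "coefficients": [
   0.0048,
   -0.0017
  ],
  "intercept": 3.6759,
  "form": "y = 3.6759 + 0.0048*x1 - 0.0017*x2"
 },
 "MF2": {
  "feature_names": [
   "total_area",
   "perimeter",
   "hull_area"
  ],
  "coefficients": [
   0.0062,
   0.0036,
   -0.0011
  ],
  "intercept": 2.9822,
  "form": "y = 2.9822 + 0.0062*x1 + 0.0036*x2 - 0.0011*x3"
 },
 "MF3": {
  "feature_names": [
   "total_area",
   "rect_height",
   "hull_area",
   "green_value"
  ],
  "coefficients": [
   0.0057,
   0.015,
   -0.0006,
   0.0405
  ],
  "intercept": 2.0999,
  "form": "y = 2.0999 + 0.0057*x1 + 0.0150*x2 - 0.0006*x3 + 0.0405*x4"
 },
 "MF4": {
  "feature_names": [
   "total_area",
   "perimeter",
   "rect_height",
   "hull_area",
   "green_value"
  ],
  "coefficients": [
   0.0063,
   0.0025,
   -0.0097,
   -0.0008,
   0.0434
  ],
  "intercept": 2.4355,
  "form": "y = 2.4355 + 0.0063*x1 + 0.0025*x2 - 0.0097*x3 - 0.0008*x4 + 0.0434*x5"
 },
 "MF5": {
  "feature_names": [
   "total_area",
   "perimeter",
   "rect_width",
   "rect_height",
   "hull_area",
   "green_value"
  ],
  "coefficients": [
   0.0058,
   0.0008,
   -0.0024,
   0.0138,
   -0.0007,
   0.0394
  ],
  "intercept": 2.1262,
  "form": "y = 2.1262 + 0.0058*x1 + 0.0008*x2 - 0.0024*x3 + 0.0138*x4 - 0.0007*x5 + 0.0394*x6"
 }
}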