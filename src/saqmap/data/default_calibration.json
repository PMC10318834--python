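{
 "cuts": {
  "ad": [
   0.38541687825131393,
   1.2310291467908194,
   1.888029053678138,
   2.6239376072017215
  ],
  "mo": [
   0.44171320775853024,
   1.3281696146224413,
   1.888029053678138,
   2.6239376072017215
  ],
  "pd": [
   0.11184112760582471,
   1.020662100429323,
   1.7054675529041674,
   2.3295728202484254
  ],
  "sc": [
   1.020662100429323,
   1.7054675529041674,
   2.3295728202484254,
   2.8933390272495063
  ],
  "ua": [
   0.38541687825131393,
   1.2310291467908194,
   1.7907565284960552,
   2.4552036396216863
  ]
 },
 "diagnostics": {
  "ceiling": 0.30402,
  "mean_change": 0.12559910577928096,
  "n_batch": 50000,
  "objective": 1.4590795690097271,
  "spearman_af": 0.6675999897302406,
  "spearman_as": 0.6502000006000865,
  "spearman_dp": 0.7093000047564847,
  "spearman_pl": 0.6415999873348741,
  "spearman_ts": 0.6184000009107385,
  "utility_mean": 0.8793895199999999,
  "utility_sd": 0.14675016822535367
 },
 "followup_shift": 0.7863805908709764,
 "key": "9b525fb1e9290aca",
 "lam": {
  "af": 0.832306652292609,
  "as": 0.8262548814564943,
  "dp": 0.8796060465127229,
  "pl": 0.7990061481446029,
  "ts": 0.7753045426458123
 },
 "loading": {
  "ad": 0.7350938314868789,
  "mo": 0.7350938314868789,
  "pd": 0.7350938314868789,
  "sc": 0.35,
  "ua": 0.7350938314868789
 },
 "subscale_norm": {
  "af": [
   67.12372651365445,
   33.312895021885105
  ],
  "as": [
   29.668011913472068,
   48.90342060535963
  ],
  "dp": [
   51.800530935718896,
   13.774124675505979
  ],
  "pl": [
   70.96484228829019,
   14.726042475234959
  ],
  "ts": [
   67.6997167000217,
   11.649707188526978
  ]
 }
}
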