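{
  "provenance": "Coefficients of the published SAQ to EQ-5D-5L (China) mapping study, pooled sample N = 380; values as printed, 4 decimal places. Direct-approach columns regress utility on the five SAQ subscales scaled to 0-1; indirect-approach blocks are per-dimension ordered logits with three cut points. Standard errors stored alongside.",
  "covariate_order": ["pl", "as", "af", "ts", "dp"],
  "direct": {
    "ols": {
      "coef": {"const": 0.3046, "pl": 0.5271, "as": 0.0381, "af": 0.0538, "ts": 0.1018, "dp": 0.1491},
      "se": {"const": 0.0345, "pl": 0.0371, "as": 0.0213, "af": 0.0255, "ts": 0.0602, "dp": 0.0529}
    },
    "tobit": {
      "coef": {"const": 0.1855, "pl": 0.6040, "as": 0.0934, "af": 0.0838, "ts": 0.1211, "dp": 0.2431},
      "se": {"const": 0.0452, "pl": 0.0471, "as": 0.0299, "af": 0.0323, "ts": 0.0767, "dp": 0.0680}
    },
    "glm": {
      "coef": {"const": -0.7661, "pl": 0.5712, "as": 0.0431, "af": 0.0634, "ts": 0.0939, "dp": 0.1890},
      "se": {"const": 0.0425, "pl": 0.0462, "as": 0.0244, "af": 0.0313, "ts": 0.0728, "dp": 0.0650}
    },
    "clad": {
      "coef": {"const": 0.4421, "pl": 0.2603, "as": 0.0276, "af": 0.0983, "ts": 0.1737, "dp": 0.1343},
      "se": {"const": 0.0317, "pl": 0.0329, "as": 0.0207, "af": 0.0249, "ts": 0.0573, "dp": 0.0471}
    },
    "rmm": {
      "coef": {"const": 0.5844, "pl": 0.1500, "as": 0.0303, "af": 0.0674, "ts": 0.0214, "dp": 0.2725},
      "se": {"const": 0.0388, "pl": 0.0363, "as": 0.0135, "af": 0.0276, "ts": 0.0629, "dp": 0.0498}
    }
  },
  "betamix": {
    "c1_mu": {
      "coef": {"const": -1.5982, "pl": 3.7922, "as": 0.4226, "af": 0.6138, "ts": 0.6172, "dp": 1.3959},
      "se": {"const": 0.3250, "pl": 0.3346, "as": 0.2691, "af": 0.2241, "ts": 0.5729, "dp": 0.4715}
    },
    "pm_ub": {
      "coef": {"const": -13.9807, "pl": 5.3271, "as": 1.4955, "af": 1.9211, "ts": 1.9462, "dp": 10.2317},
      "se": {"const": 2.0050, "pl": 1.6583, "as": 0.7072, "af": 1.0112, "ts": 2.5628, "dp": 2.4454}
    }
  },
  "aldvmm": {
    "com1": {
      "coef": {"const": 0.6063, "pl": 0.0834, "as": 0.0529, "af": 0.0557, "ts": 0.0087, "dp": 0.3462},
      "se": {"const": 0.0617, "pl": 0.0548, "as": 0.0281, "af": 0.0360, "ts": 0.0753, "dp": 0.0621}
    },
    "com2": {
      "coef": {"const": -0.0005, "pl": 0.8770, "as": 0.0821, "af": 0.0973, "ts": 0.2256, "dp": 0.0341},
      "se": {"const": 0.0801, "pl": 0.0730, "as": 0.0606, "af": 0.0582, "ts": 0.1383, "dp": 0.1164}
    }
  },
  "indirect": {
    "mo": {
      "beta": {"pl": -12.6193, "as": -1.2609, "af": -1.4301, "ts": -4.4563, "dp": 3.1240},
      "beta_se": {"pl": 1.3646, "as": 0.7910, "af": 0.7593, "ts": 1.7579, "dp": 1.5290},
      "cuts": [-10.2116, -6.5813, -3.3392],
      "cuts_se": [1.2489, 1.1164, 1.2704]
    },
    "sc": {
      "beta": {"pl": -11.5837, "as": -0.4644, "af": -2.6338, "ts": -2.3537, "dp": 5.0511},
      "beta_se": {"pl": 2.0187, "as": 1.7335, "af": 1.4914, "ts": 3.3780, "dp": 2.7691},
      "cuts": [-4.5555, -1.9126, -1.2472],
      "cuts_se": [1.8417, 1.8522, 1.9092]
    },
    "ua": {
      "beta": {"pl": -10.2628, "as": -1.0368, "af": -1.4646, "ts": -3.8393, "dp": 0.2211},
      "beta_se": {"pl": 1.1946, "as": 0.6768, "af": 0.6879, "ts": 1.6251, "dp": 1.4063},
      "cuts": [-10.3147, -6.5026, -3.4244],
      "cuts_se": [1.1832, 1.0379, 1.1673]
    },
    "pd": {
      "beta": {"pl": -4.4646, "as": -1.3777, "af": -1.6318, "ts": -3.6361, "dp": -5.2587},
      "beta_se": {"pl": 1.0459, "as": 0.5914, "af": 0.6454, "ts": 1.5482, "dp": 1.3923},
      "cuts": [-10.3706, -6.4055, -2.6310],
      "cuts_se": [1.1160, 0.9733, 1.1236]
    },
    "ad": {
      "beta": {"pl": -0.8718, "as": -0.7419, "af": -1.5527, "ts": 2.6952, "dp": -10.6382},
      "beta_se": {"pl": 0.9153, "as": 0.5756, "af": 0.6109, "ts": 1.4271, "dp": 1.4331},
      "cuts": [-5.3762, -3.4332, 1.7840],
      "cuts_se": [0.9003, 0.8653, 1.2772]
    }
  }
}
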