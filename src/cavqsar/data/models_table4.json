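{
  "A": {
    "name": "Model A (CaV activation)",
    "intercept": -3.1819,
    "coefficients": {
      "k2alpha": -0.0413,
      "Id": -0.0003,
      "IdwAverage": 0.553
    },
    "metadata": {
      "source": "Table 4",
      "response": "pIC50 (CaV activation)",
      "n_train": 20,
      "n_test": 4,
      "p": 3,
      "published_stats": {
        "f_stat": 3.9664,
        "r2": 0.3182,
        "q2": 0.0693,
        "r2_pred": 0.9586,
        "r2_se": 0.0933,
        "q2_se": 0.109,
        "r2_pred_se": 0.0204
      },
      "published_stats_status": {
        "r2": "reproduced",
        "r2_pred": "reproduced",
        "r2_se": "reproduced_with_df_n_minus_p",
        "f_stat": "printed_unreproduced",
        "q2": "printed_unreproduced",
        "q2_se": "printed_unreproduced",
        "r2_pred_se": "printed_unreproduced"
      }
    }
  },
  "B": {
    "name": "Model B (CaV inhibition)",
    "intercept": 1.9116,
    "coefficients": {
      "Most+vePotential": 0.3241,
      "MomInertiaY": 0.0,
      "DeltaEpsilonC": -0.36
    },
    "metadata": {
      "source": "Table 4",
      "response": "pIC50 (CaV inhibition)",
      "n_train": 20,
      "n_test": 3,
      "p": 3,
      "published_stats": {
        "f_stat": 1.5682,
        "r2": 0.0845,
        "q2": 0.1148,
        "r2_pred": 0.5227,
        "r2_se": 0.0804,
        "q2_se": 0.0887,
        "r2_pred_se": 0.0387
      },
      "published_stats_status": {
        "f_stat": "printed_unreproduced",
        "r2": "printed_unreproduced",
        "q2": "printed_unreproduced",
        "r2_pred": "printed_unreproduced",
        "r2_se": "printed_unreproduced",
        "q2_se": "printed_unreproduced",
        "r2_pred_se": "printed_unreproduced"
      }
    }
  }
}
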