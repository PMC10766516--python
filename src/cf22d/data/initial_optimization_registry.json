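{
  "name": "initial_optimization",
  "comment": "Printed organisation of the initial optimisation manifest: 79 training data sets (1,886 data, drawn from the 418-datum atomic/molecular-energy collection plus main-group selections) and 13 validation data sets (1,808 data); five rounds of performance-triggered promotion later moved 10 of the validation sets (1,033 data) into training.",
  "sub_databases": [
    {
      "name": "initial_training",
      "unit": "kcal/mol",
      "size": 1886,
      "members": [
        {"id": "AME418", "size": 418, "n_train": 418, "n_test": 0, "class": "TC", "n_sets": 26},
        {"id": "MGCDB84_selection", "size": 1468, "n_train": 1468, "n_test": 0, "class": "TC", "n_sets": 53}
      ]
    },
    {
      "name": "initial_validation",
      "unit": "kcal/mol",
      "size": 1808,
      "members": [
        {"id": "validation_sets_80_92", "size": 1808, "n_train": 0, "n_test": 1808, "class": "TC", "n_sets": 13}
      ]
    }
  ]
}
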