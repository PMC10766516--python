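{
  "name": "ddb22",
  "comment": "Printed composition of the consolidated benchmark collection: four sub-databases; the ground-state sub-database is broken down by property class with its printed training/testing split.",
  "sub_databases": [
    {
      "name": "GSE6075",
      "unit": "kcal/mol",
      "size": 6075,
      "members": [
        {"id": "BH318", "size": 318, "n_train": 206, "n_test": 112, "class": "BH", "n_sets": 13},
        {"id": "NC2805", "size": 2805, "n_train": 936, "n_test": 1869, "class": "NC", "n_sets": 44},
        {"id": "IE1119", "size": 1119, "n_train": 293, "n_test": 826, "class": "IE", "n_sets": 30},
        {"id": "TC1833", "size": 1833, "n_train": 1431, "n_test": 402, "class": "TC", "n_sets": 55}
      ]
    },
    {
      "name": "EE157",
      "unit": "eV",
      "size": 157,
      "members": [
        {"id": "EE157_all", "size": 157, "n_train": 0, "n_test": 157, "class": "EE", "n_sets": 10}
      ]
    },
    {
      "name": "MS261",
      "unit": "angstrom",
      "size": 261,
      "members": [
        {"id": "MS261_all", "size": 261, "n_train": 0, "n_test": 261, "class": "MS", "n_sets": 5}
      ]
    },
    {
      "name": "DM79",
      "unit": "debye",
      "size": 79,
      "members": [
        {"id": "DM79_all", "size": 79, "n_train": 0, "n_test": 79, "class": "DM", "n_sets": 1}
      ]
    }
  ]
}
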