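{
  "organs": {
    "kidney": {
      "before": ["donor", "new", "matching", "failing", "replacement", "deceased"],
      "after": ["transplant", "transplants", "transplantation", "failure", "disease", "donor", "surgery", "recipient", "dialysis"]
    },
    "liver": {
      "before": ["donor", "new", "matching", "failing", "replacement", "deceased"],
      "after": ["transplant", "transplants", "transplantation", "failure", "disease", "donor", "surgery", "recipient", "cirrhosis"]
    },
    "heart": {
      "before": ["donor", "new", "matching", "failing", "replacement", "deceased"],
      "after": ["transplant", "transplants", "transplantation", "failure", "disease", "donor", "surgery", "recipient", "cardiomyopathy"]
    },
    "lung": {
      "before": ["donor", "new", "matching", "failing", "replacement", "deceased"],
      "after": ["transplant", "transplants", "transplantation", "failure", "disease", "donor", "surgery", "recipient", "fibrosis"]
    },
    "pancreas": {
      "before": ["donor", "new", "matching", "failing", "replacement", "deceased"],
      "after": ["transplant", "transplants", "transplantation", "failure", "disease", "donor", "surgery", "recipient", "pancreatitis"]
    },
    "intestine": {
      "before": ["donor", "new", "matching", "failing", "replacement", "deceased"],
      "after": ["transplant", "transplants", "transplantation", "failure", "disease", "donor", "surgery", "recipient", "resection"]
    },
    "bone_marrow": {
      "before": ["donor", "new", "matching", "failing", "replacement", "deceased"],
      "after": ["transplant", "transplants", "transplantation", "failure", "disease", "donor", "surgery", "recipient", "biopsy", "match"]
    }
  },
  "solid": ["heart", "lung", "kidney", "liver", "pancreas"],
  "compounds": [["bone marrow", "bone_marrow"]]
}
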