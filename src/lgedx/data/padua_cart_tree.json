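{
  "metadata": {
    "provenance": "fixed-from-paper",
    "note": "Published CART flowchart over segmental LGE features. The split conditions (anteroseptal LV-LGE; >=5 and >=2 mid-myocardial LV segments; >=16 LV segments; >=2 RV segments; inferolateral LV-LGE) are as published; the leaf labels of the final inferolateral split are a reconstruction from the per-differential discriminators.",
    "final_leaf_reconstructed": true
  },
  "root": {
    "node_id": "n0",
    "feature": "anteroseptal_lv",
    "op": "ge",
    "threshold": 0.5,
    "if_false": {
      "node_id": "n1",
      "feature": "lv_midmyo_count",
      "op": "ge",
      "threshold": 5,
      "if_true": {"node_id": "n1a", "leaf": "myocarditis"},
      "if_false": {
        "node_id": "n2",
        "feature": "lv_midmyo_count",
        "op": "ge",
        "threshold": 2,
        "if_true": {"node_id": "n2a", "leaf": "DCM"},
        "if_false": {"node_id": "n2b", "leaf": "ARVC"}
      }
    },
    "if_true": {
      "node_id": "n3",
      "feature": "lv_segment_count",
      "op": "ge",
      "threshold": 16,
      "if_true": {"node_id": "n3a", "leaf": "amyloidosis"},
      "if_false": {
        "node_id": "n4",
        "feature": "rv_segment_count",
        "op": "ge",
        "threshold": 2,
        "if_true": {"node_id": "n4a", "leaf": "sarcoidosis"},
        "if_false": {
          "node_id": "n5",
          "feature": "inferolateral_lv",
          "op": "ge",
          "threshold": 0.5,
          "if_true": {"node_id": "n5a", "leaf": "ARVC"},
          "if_false": {"node_id": "n5b", "leaf": "DCM"}
        }
      }
    }
  }
}
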