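{
  "comment": "Binding-pocket specificity motifs for Cache-superfamily sensory domains. Positions are 1-based residue numbers on the named packaged reference (see references.fasta). References are synthetic scaffolds carrying published pocket residues at published numbering; entries whose residue identities are not printed in the main text are stamped provenance accordingly and are editable without code changes.",
  "references": {
    "A4_dCache_1UR": {
      "family": "dCache_1",
      "documented_specificity": [
        {"module": "distal", "ligand_class": "pyrimidine", "sub_specificity": "uracil"},
        {"module": "proximal", "ligand_class": "carboxylic acid", "sub_specificity": "SCFA"}
      ]
    },
    "McpX_like_dCache_1AM": {
      "family": "dCache_1",
      "documented_specificity": [
        {"module": "distal", "ligand_class": "amine", "sub_specificity": null}
      ]
    },
    "PctA_like_dCache_1AA": {
      "family": "dCache_1",
      "documented_specificity": [
        {"module": "distal", "ligand_class": "amino acid", "sub_specificity": null},
        {"module": "proximal", "ligand_class": "carboxylic acid", "sub_specificity": "SCFA"}
      ]
    },
    "McpH_like_dCache_1PU": {
      "family": "dCache_1",
      "documented_specificity": [
        {"module": "distal", "ligand_class": "purine", "sub_specificity": null}
      ]
    },
    "K1_sCache_2": {
      "family": "sCache_2",
      "documented_specificity": [
        {"module": "mono", "ligand_class": "carboxylic acid", "sub_specificity": "L-lactate"}
      ]
    },
    "FHS_sCache_3_3": {
      "family": "sCache_3_3",
      "documented_specificity": [
        {"module": "mono", "ligand_class": "carboxylic acid", "sub_specificity": "formate"}
      ]
    }
  },
  "motifs": [
    {
      "motif_id": "dCache_1UR_distal_uracil",
      "family": "dCache_1",
      "reference_id": "A4_dCache_1UR",
      "module": "distal",
      "ligand_class": "pyrimidine",
      "sub_specificity": "uracil",
      "provenance": "results_text",
      "positions": [
        {"pos": 116, "allowed": ["R"], "role": "required"},
        {"pos": 129, "allowed": ["F", "Y"], "role": "required"},
        {"pos": 145, "allowed": ["T"], "role": "required"},
        {"pos": 160, "allowed": ["W"], "role": "required"},
        {"pos": 176, "allowed": ["Y"], "role": "required"},
        {"pos": 178, "allowed": ["N"], "role": "required"},
        {"pos": 180, "allowed": ["N"], "role": "required"},
        {"pos": 205, "allowed": ["D"], "role": "required"}
      ],
      "determinant_rules": {}
    },
    {
      "motif_id": "dCache_1AM_distal_amine",
      "family": "dCache_1",
      "reference_id": "McpX_like_dCache_1AM",
      "module": "distal",
      "ligand_class": "amine",
      "sub_specificity": null,
      "provenance": "supplementary_placeholder",
      "positions": [
        {"pos": 116, "allowed": ["D"], "role": "required"},
        {"pos": 129, "allowed": ["F", "Y"], "role": "required"},
        {"pos": 145, "allowed": ["A"], "role": "required"},
        {"pos": 160, "allowed": ["W"], "role": "required"},
        {"pos": 176, "allowed": ["Y"], "role": "required"},
        {"pos": 178, "allowed": ["W"], "role": "required"},
        {"pos": 180, "allowed": ["Y"], "role": "required"},
        {"pos": 205, "allowed": ["D"], "role": "required"}
      ],
      "determinant_rules": {}
    },
    {
      "motif_id": "dCache_1AA_distal_amino_acid",
      "family": "dCache_1",
      "reference_id": "PctA_like_dCache_1AA",
      "module": "distal",
      "ligand_class": "amino acid",
      "sub_specificity": null,
      "provenance": "supplementary_placeholder",
      "positions": [
        {"pos": 116, "allowed": ["Y"], "role": "required"},
        {"pos": 129, "allowed": ["F", "Y"], "role": "required"},
        {"pos": 145, "allowed": ["S"], "role": "required"},
        {"pos": 160, "allowed": ["W"], "role": "required"},
        {"pos": 176, "allowed": ["Y"], "role": "required"},
        {"pos": 178, "allowed": ["T"], "role": "required"},
        {"pos": 180, "allowed": ["W"], "role": "required"},
        {"pos": 205, "allowed": ["D"], "role": "required"}
      ],
      "determinant_rules": {}
    },
    {
      "motif_id": "dCache_1PU_distal_purine",
      "family": "dCache_1",
      "reference_id": "McpH_like_dCache_1PU",
      "module": "distal",
      "ligand_class": "purine",
      "sub_specificity": null,
      "provenance": "supplementary_placeholder",
      "positions": [
        {"pos": 116, "allowed": ["N"], "role": "required"},
        {"pos": 129, "allowed": ["F", "Y"], "role": "required"},
        {"pos": 145, "allowed": ["D"], "role": "required"},
        {"pos": 160, "allowed": ["W"], "role": "required"},
        {"pos": 176, "allowed": ["Y"], "role": "required"},
        {"pos": 178, "allowed": ["S"], "role": "required"},
        {"pos": 180, "allowed": ["F"], "role": "required"},
        {"pos": 205, "allowed": ["D"], "role": "required"}
      ],
      "determinant_rules": {}
    },
    {
      "motif_id": "dCache_1_proximal_scfa",
      "family": "dCache_1",
      "reference_id": "A4_dCache_1UR",
      "module": "proximal",
      "ligand_class": "carboxylic acid",
      "sub_specificity": "SCFA",
      "provenance": "results_text",
      "positions": [
        {"pos": 225, "allowed": ["Y"], "role": "required"},
        {"pos": 238, "allowed": ["H"], "role": "required"},
        {"pos": 273, "allowed": ["Y"], "role": "required"},
        {"pos": 280, "allowed": ["K"], "role": "required"}
      ],
      "determinant_rules": {}
    },
    {
      "motif_id": "sCache_2_scca",
      "family": "sCache_2",
      "reference_id": "K1_sCache_2",
      "module": "mono",
      "ligand_class": "carboxylic acid",
      "sub_specificity": null,
      "provenance": "results_text",
      "positions": [
        {"pos": 101, "allowed": ["Y"], "role": "required"},
        {"pos": 103, "allowed": ["F", "W", "Y"], "role": "required"},
        {"pos": 114, "allowed": ["L", "H"], "role": "determinant"},
        {"pos": 135, "allowed": ["M"], "role": "accessory"},
        {"pos": 153, "allowed": ["F", "Y"], "role": "required"},
        {"pos": 155, "allowed": ["F", "W"], "role": "accessory"},
        {"pos": 166, "allowed": ["K"], "role": "required"}
      ],
      "determinant_rules": {
        "114": {"L": "L-lactate", "H": "pyruvate"}
      }
    },
    {
      "motif_id": "sCache_3_3_formate",
      "family": "sCache_3_3",
      "reference_id": "FHS_sCache_3_3",
      "module": "mono",
      "ligand_class": "carboxylic acid",
      "sub_specificity": "formate",
      "provenance": "external",
      "positions": [
        {"pos": 88, "allowed": ["Y"], "role": "required"},
        {"pos": 92, "allowed": ["R"], "role": "required"},
        {"pos": 118, "allowed": ["K"], "role": "required"},
        {"pos": 143, "allowed": ["Y"], "role": "required"}
      ],
      "determinant_rules": {}
    }
  ]
}
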