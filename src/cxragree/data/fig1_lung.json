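{
  "name": "fig1_lung",
  "description": "Lung-tissue subtree of the diagnostic labeling scheme: the 20 annotatable labels with their hierarchy, plus the merged costophrenic-angle/effusion category.",
  "labels": [
    {"id": "Normal", "name": "Normal"},
    {"id": "Increased Translucency", "name": "Increased Translucency"},
    {"id": "Pneumothorax", "name": "Pneumothorax", "parent": "Increased Translucency"},
    {"id": "Cyst/Bullae", "name": "Cyst/Bullae", "parent": "Increased Translucency"},
    {"id": "Emphysema", "name": "Emphysema", "parent": "Increased Translucency"},
    {"id": "Decreased Translucency", "name": "Decreased Translucency"},
    {"id": "Infiltrate", "name": "Infiltrate", "parent": "Decreased Translucency"},
    {"id": "Infection", "name": "Infection", "parent": "Infiltrate"},
    {"id": "Abscess", "name": "Abscess", "parent": "Infiltrate"},
    {"id": "Tuberculosis", "name": "Tuberculosis", "parent": "Infiltrate"},
    {"id": "Malignant", "name": "Malignant", "parent": "Decreased Translucency"},
    {"id": "Diffuse Lung Changes", "name": "Diffuse Lung Changes"},
    {"id": "Fibrosis", "name": "Fibrosis", "parent": "Diffuse Lung Changes"},
    {"id": "Chronic Lung Changes", "name": "Chronic Lung Changes", "parent": "Diffuse Lung Changes"},
    {"id": "Stasis/Edema", "name": "Stasis/Edema"},
    {"id": "Costophrenic Angle Blunting", "name": "Costophrenic Angle Blunting"},
    {"id": "Pleural Effusion", "name": "Pleural Effusion"},
    {"id": "Atelectasis", "name": "Atelectasis"},
    {"id": "Pleural Thickening/Changes", "name": "Pleural Thickening/Changes"},
    {"id": "Former Operation in Lung Tissue", "name": "Former Operation in Lung Tissue"}
  ],
  "composites": [
    {
      "id": "Costophrenic Angle Blunting AND Pleural Effusion",
      "members": ["Costophrenic Angle Blunting", "Pleural Effusion"]
    }
  ]
}
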