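{
  "name": "fig6_lung_synthetic",
  "description": "PROVISIONAL / SYNTHETIC revision of the lung-tissue scheme in which the interpretive leaves under 'Infiltrate' are replaced by descriptive appearance labels. The published revision is figure-only content; this fixture is a best-effort reconstruction of its intent, not a faithful copy, and is marked synthetic for that reason.",
  "provisional": true,
  "labels": [
    {"id": "Normal", "name": "Normal"},
    {"id": "Increased Translucency", "name": "Increased Translucency"},
    {"id": "Pneumothorax", "name": "Pneumothorax", "parent": "Increased Translucency"},
    {"id": "Cyst/Bullae", "name": "Cyst/Bullae", "parent": "Increased Translucency"},
    {"id": "Emphysema", "name": "Emphysema", "parent": "Increased Translucency"},
    {"id": "Decreased Translucency", "name": "Decreased Translucency"},
    {"id": "Infiltrate", "name": "Infiltrate", "parent": "Decreased Translucency"},
    {"id": "Consolidation", "name": "Consolidation", "parent": "Infiltrate"},
    {"id": "Ground-Glass Opacity", "name": "Ground-Glass Opacity", "parent": "Infiltrate"},
    {"id": "Nodule/Mass", "name": "Nodule/Mass", "parent": "Decreased Translucency"},
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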