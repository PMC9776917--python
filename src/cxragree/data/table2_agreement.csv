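category,kappa,ci_low,ci_high,ppa,pna
Normal,0.79,0.71,0.86,0.59,0.94
Increased Translucency incl. sub-categories,0.73,0.64,0.81,0.47,0.92
Increased Translucency,0.88,0.83,0.93,0,0.97
Pneumothorax,0.83,0.76,0.91,0.53,0.95
Cyst/Bullae,0.98,0.95,1.00,0.1,0.99
Emphysema,0.95,0.91,0.99,0.05,0.99
Decreased Translucency incl. sub-categories,0.55,0.45,0.64,0.84,0.59
Decreased Translucency,0.46,0.38,0.55,0.13,0.84
Infiltrate incl. sub-categories,0.40,0.31,0.48,0.50,0.78
Infiltrate,0.49,0.40,0.58,0.34,0.84
Infection,0.67,0.60,0.75,0.11,0.91
Abscess,0.97,0.95,1.00,0,0.99
Tuberculosis,0.99,0.98,1.00,0,1
Malignant,0.87,0.82,0.93,0.33,0.97
Diffuse Lung Changes incl. sub-categories,0.54,0.45,0.63,0.40,0.85
Diffuse Lung Changes,0.70,0.62,0.78,0.12,0.92
Fibrosis,0.95,0.91,0.99,0.28,0.99
Chronic Lung Changes,0.94,0.90,0.98,0,0.98
Stasis/Edema,0.79,0.71,0.86,0.31,0.94
Costophrenic Angle Blunting,0.58,0.49,0.67,0.25,0.88
Pleural Effusion,0.61,0.51,0.71,0.61,0.87
Costophrenic Angle Blunting AND Pleural Effusion,0.53,0.43,0.62,0.67,0.81
Atelectasis,0.40,0.30,0.50,0.32,0.81
Pleural Thickening/Changes,0.88,0.83,0.94,0.20,0.97
Former Operation in Lung Tissue,0.94,0.90,0.98,0.04,0.98
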