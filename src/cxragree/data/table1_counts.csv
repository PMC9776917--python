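label,Novice 1,Novice 2,Intermediate 1,Intermediate 2,Experienced 1,Experienced 2
Normal,4,11,11,19,11,23
Increased Translucency,7,3,8,0,0,0
Pneumothorax,5,8,11,10,10,9
Cyst/Bullae,0,1,1,0,5,2
Emphysema,0,1,0,3,4,0
Decreased Translucency,51,31,11,0,0,0
Infiltrate,21,12,24,33,24,2
Infection,0,2,3,6,30,13
Abscess,0,0,0,1,0,3
Tuberculosis,0,0,1,0,0,0
Malignant,3,6,1,10,5,3
Diffuse Lung Changes,26,6,7,11,0,1
Fibrosis,1,2,2,2,1,2
Chronic Lung Changes,1,0,1,0,5,2
Stasis/Edema,5,7,9,6,10,9
Costophrenic Angle Blunting,31,21,24,5,3,0
Pleural Effusion,8,22,32,24,38,27
Atelectasis,14,22,13,9,50,25
Pleural Thickening/Changes,0,7,3,5,3,4
Former Operation in Lung Tissue,0,5,3,5,0,0
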