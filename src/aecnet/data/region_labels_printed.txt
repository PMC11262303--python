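L Amygdala
R Amygdala
L Angular
R Angular
L Calcarine S
R Calcarine S
L Caudate Nucleus
R Caudate
L MCC
R MCC
L PCC
R PCC
L Mid Frontal C
R Mid Frontal C
L Sup Frontal C
R Sup Frontal C
R Hippocampus
R Hippocampus
L Insula
R Insula
L Ant OFC
L Lat OFC
R Lat OFC
L Med OFC
R Med OFC
L Post OFC
R post OFC
L ParaHippocampal C
R ParaHippocampal C
L Inf Parietal C
R Inf Parietal C
L Sup Parietal C
R Sup Parietal C
L Putamen
R Putamen
L Inf Temporal C
R Inf Temporal C
L Mid Temporal
R Mid Temporal c
L Sup Temporal C
L Ant OFC
L VTA
R VTA
Vermis
Thalamus
Nucleus Accumbens
L Lingual
R Lingual
L ACC
R ACC
L Cerebellum
R Cerebellum
L Cerebellum Crus
R Cerebellum Crus
L Inf Frontal C
R Inf Frontal C
L Vm Frontal C
R Vm Frontal C
L Dm Frontal C
R Dm Frontal C
R Sup Temporal C
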