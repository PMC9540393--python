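R Precentral Gyrus
R Superior Frontal Gyrus, Dorsolateral
R Superior Frontal Gyrus, Orbital Part
R Middle Frontal Gyrus
R Middle Frontal Gyrus, Orbital Part
R Inferior Frontal Gyrus, Opercular Part
R Inferior Frontal Gyrus, Triangular Part
R Inferior Frontal Gyrus, Orbital Part
R Rolandic Operculum
R Supplementary Motor Area
R Olfactory Cortex
R Superior Frontal Gyrus, Medial
R Superior Frontal Gyrus, Medial Orbital
R Gyrus Rectus
R Insula
R Anterior Cingulate and Paracingulate Gyri
R Median Cingulate and Paracingulate Gyri
R Posterior Cingulate Gyrus
R Hippocampus
R Parahippocampal Gyrus
R Amygdala
R Calcarine Fissure
R Cuneus
R Lingual Gyrus
R Superior Occipital Gyrus
R Middle Occipital Gyrus
R Inferior Occipital Gyrus
R Fusiform Gyrus
R Postcentral Gyrus
R Superior Parietal Gyrus
R Inferior Parietal Gyri
R Supramarginal Gyrus
R Angular Gyrus
R Precuneus
R Paracentral Lobule
R Caudate Nucleus
R Lenticular Nucleus, Putamen
R Lenticular Nucleus, Pallidum
R Thalamus
R Heschl Gyrus
R Superior Temporal Gyrus
R Temporal Pole: Superior Temporal Gyrus
R Middle Temporal Gyrus
R Temporal Pole: Middle Temporal Gyrus
R Inferior Temporal Gyrus
L Inferior Temporal Gyrus
L Temporal Pole: Middle Temporal Gyrus
L Middle Temporal Gyrus
L Temporal Pole: Superior Temporal Gyrus
L Superior Temporal Gyrus
L Heschl Gyrus
L Thalamus
L Lenticular Nucleus, Pallidum
L Lenticular Nucleus, Putamen
L Caudate Nucleus
L Paracentral Lobule
L Precuneus
L Angular Gyrus
L Supramarginal Gyrus
L Inferior Parietal Gyri
L Superior Parietal Gyrus
L Postcentral Gyrus
L Fusiform Gyrus
L Inferior Occipital Gyrus
L Middle Occipital Gyrus
L Superior Occipital Gyrus
L Lingual Gyrus
L Cuneus
L Calcarine Fissure
L Amygdala
L Parahippocampal Gyrus
L Hippocampus
L Posterior Cingulate Gyrus
L Median Cingulate and Paracingulate Gyri
L Anterior Cingulate and Paracingulate Gyri
L Insula
L Gyrus Rectus
L Superior Frontal Gyrus, Medial Orbital
L Superior Frontal Gyrus, Medial
L Olfactory Cortex
L Supplementary Motor Area
L Rolandic Operculum
L Inferior Frontal Gyrus, Orbital Part
L Inferior Frontal Gyrus, Triangular Part
L Inferior Frontal Gyrus, Opercular Part
L Middle Frontal Gyrus, Orbital Part
L Middle Frontal Gyrus
L Superior Frontal Gyrus, Orbital Part
L Superior Frontal Gyrus, Dorsolateral
L Precentral Gyrus
R Cerebellum Crus I
R Cerebellum Crus II
R Cerebellum Lobule III
R Cerebellum Lobules IV and V
R Cerebellum Lobule VI
R Cerebellum Lobule VIIb
R Cerebellum Lobule VIII
R Cerebellum Lobule IX
R Cerebellum Lobule X
L Cerebellum Crus I
L Cerebellum Crus II
L Cerebellum Lobule III
L Cerebellum Lobules IV and V
L Cerebellum Lobule VI
L Cerebellum Lobule VIIb
L Cerebellum Lobule VIII
L Cerebellum Lobule IX
L Cerebellum Lobule X
Vermis Lobules I and II
Vermis Lobule III
Vermis Lobules IV and V
Vermis Lobule VI
Vermis Lobule VII
Vermis Lobule VIII
Vermis Lobule IX
Vermis Lobule X
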