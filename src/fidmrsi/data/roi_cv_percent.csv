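# Transcription of the published per-ROI inter-subject CV table (percent)
# for the five qualified metabolites in the 44 qualified ROIs.
# Values are integers as printed; summary rows are recomputed, not stored.
roi,tCho,tCr,Glu,mIns,NAA
Subcortical WM (left),7,7,7,8,7
Subcortical WM (right),6,6,8,6,6
Subcortical WM (bilateral),6,6,7,7,6
Motor subcortex WM,8,7,7,7,7
Motor cortex GM,6,8,8,8,9
Motor cortex/subcortex GM+WM,7,7,7,8,8
Parietal subcortex WM,11,10,10,10,10
Parietal cortex GM,10,10,11,10,11
Parietal cortex/subcortex GM+WM,10,10,11,10,11
Cingulate subcortex WM,9,10,12,10,9
Cingulate cortex GM,9,10,12,10,10
Cingulate cortex/subcortex GM+WM,9,10,12,10,9
Visual subcortex WM,13,15,14,14,8
Primary somatosensory subcortex WM,8,9,8,10,8
Primary somatosensory cortex/subcortex GM+WM,8,9,8,10,9
Thalamus,19,20,21,19,16
Putamen,9,9,15,13,11
Non-lobe WM,10,7,15,10,8
Cortical GM (left),7,8,7,8,8
Cortical GM (right),6,6,7,6,6
Cortical GM (bilateral),6,6,7,7,7
Cortical GM + subcortical WM (left),7,7,7,8,8
Cortical GM + subcortical WM (right),6,6,7,6,6
Cortical GM + subcortical WM (bilateral),6,6,7,7,6
Subcortical GM (left),10,9,14,13,10
Subcortical GM (right),15,15,16,14,15
Subcortical GM (bilateral),12,11,15,13,11
Auditory subcortex WM,8,9,9,10,9
Auditory cortex GM,7,8,8,8,9
Auditory cortex/subcortex GM+WM,7,8,9,9,9
Occipital subcortex WM,12,12,12,12,7
Occipital cortex GM,11,12,10,12,7
Occipital cortex/subcortex GM+WM,11,12,11,12,6
Temporal subcortex WM,6,8,7,9,8
Temporal cortex/subcortex GM+WM,5,8,7,8,8
Frontal subcortex WM,8,7,10,9,8
Frontal cortex GM,8,7,9,8,9
Frontal cortex/subcortex GM+WM,8,7,9,9,8
Visual cortex GM,13,17,12,15,8
Visual cortex/subcortex GM+WM,13,16,12,14,7
Primary somatosensory cortex GM,8,10,9,10,9
Pallidum,14,12,24,15,19
Hippocampus,16,17,18,18,16
Corpus callosum,16,16,19,15,17
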