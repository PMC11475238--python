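# Transcription of the published per-ROI cohort mean concentration estimates
# [mM] with their standard deviations, for the five qualified metabolites in
# the 44 qualified ROIs.  Summary rows are recomputed, not stored.
roi,tCho_mean,tCho_sd,tCr_mean,tCr_sd,Glu_mean,Glu_sd,mIns_mean,mIns_sd,NAA_mean,NAA_sd
Subcortical WM (left),1.89,0.76,7.24,2.72,7.68,3.35,5.15,1.92,9.78,3.77
Subcortical WM (right),1.95,0.71,7.25,2.50,7.67,3.23,5.35,1.77,9.67,3.44
Subcortical WM (bilateral),1.92,0.73,7.24,2.62,7.67,3.29,5.24,1.85,9.73,3.61
Motor subcortex WM,2.00,0.47,7.96,1.61,7.90,2.25,5.45,1.15,10.72,2.11
Motor cortex GM,1.71,0.50,7.55,2.06,8.42,2.58,5.39,1.72,10.15,2.79
Motor cortex/subcortex GM+WM,1.87,0.50,7.78,1.83,8.13,2.41,5.42,1.43,10.48,2.44
Parietal subcortex WM,1.84,0.51,7.51,2.00,7.64,2.61,5.54,1.38,10.21,2.66
Parietal cortex GM,1.64,0.50,7.57,2.23,8.55,2.81,5.61,1.63,10.09,3.02
Parietal cortex/subcortex GM+WM,1.74,0.52,7.54,2.11,8.07,2.74,5.58,1.50,10.15,2.83
Cingulate subcortex WM,2.32,0.81,7.55,2.75,8.06,3.70,5.99,2.01,10.55,3.57
Cingulate cortex GM,2.22,0.74,8.45,2.62,10.14,3.57,6.60,2.05,10.86,3.41
Cingulate cortex/subcortex GM+WM,2.28,0.78,7.94,2.73,8.98,3.79,6.26,2.05,10.68,3.51
Visual subcortex WM,1.54,0.57,6.74,2.44,6.64,3.18,4.60,1.62,9.31,3.69
Primary somatosensory subcortex WM,1.73,0.50,7.57,1.93,7.88,2.27,5.21,1.27,10.06,2.57
Primary somatosensory cortex/subcortex GM+WM,1.65,0.52,7.40,2.14,7.90,2.48,5.16,1.46,9.73,2.84
Thalamus,2.40,0.83,8.81,3.07,9.18,4.15,6.24,2.21,10.60,4.00
Putamen,2.27,0.86,9.36,3.32,9.20,3.59,5.09,2.04,9.58,3.77
Non-lobe WM,2.42,0.76,7.59,2.53,6.18,2.75,5.34,1.71,9.88,3.14
Cortical GM (left),1.64,0.76,6.92,3.06,8.13,3.99,5.06,2.28,9.16,4.47
Cortical GM (right),1.75,0.64,7.25,2.58,8.35,3.35,5.49,1.91,9.52,3.49
Cortical GM (bilateral),1.69,0.71,7.07,2.85,8.23,3.70,5.26,2.12,9.33,4.05
Cortical GM + subcortical WM (left),1.78,0.77,7.09,2.89,7.89,3.67,5.11,2.10,9.49,4.14
Cortical GM + subcortical WM (right),1.86,0.69,7.25,2.54,7.98,3.31,5.41,1.84,9.60,3.47
Cortical GM + subcortical WM (bilateral),1.81,0.73,7.16,2.73,7.93,3.50,5.25,1.98,9.54,3.83
Subcortical GM (left),2.32,0.95,8.61,3.64,8.20,4.06,5.58,2.48,9.50,4.21
Subcortical GM (right),2.02,0.97,7.40,3.68,7.24,4.16,4.99,2.48,7.83,4.32
Subcortical GM (bilateral),2.17,0.97,7.99,3.72,7.72,4.15,5.28,2.51,8.66,4.35
Auditory subcortex WM,1.91,0.72,7.13,2.48,8.14,3.23,5.13,1.79,8.81,3.45
Auditory cortex GM,1.67,0.69,6.69,2.60,8.10,3.43,4.88,1.95,8.13,3.56
Auditory cortex/subcortex GM+WM,1.78,0.71,6.89,2.56,8.11,3.34,4.99,1.88,8.44,3.53
Occipital subcortex WM,1.61,0.68,6.61,2.66,6.68,3.35,4.59,1.79,8.83,3.91
Occipital cortex GM,1.46,0.65,6.55,2.92,7.26,3.72,4.57,2.00,8.58,4.31
Occipital cortex/subcortex GM+WM,1.54,0.67,6.58,2.79,6.95,3.55,4.58,1.89,8.71,4.12
Temporal subcortex WM,1.95,0.89,6.89,3.17,7.30,3.68,4.83,2.15,8.56,4.06
Temporal cortex/subcortex GM+WM,1.84,0.87,6.74,3.19,7.47,3.91,4.82,2.21,8.33,4.63
Frontal subcortex WM,1.99,0.79,7.39,2.69,7.99,3.41,5.20,1.92,9.91,3.81
Frontal cortex GM,1.74,0.79,6.98,3.01,8.29,3.98,5.22,2.29,9.44,3.98
Frontal cortex/subcortex GM+WM,1.88,0.80,7.21,2.84,8.12,3.67,5.21,2.09,9.70,3.89
Visual cortex GM,1.37,0.55,6.74,2.72,7.28,3.46,4.53,1.81,9.17,3.99
Visual cortex/subcortex GM+WM,1.46,0.57,6.73,2.57,6.90,3.32,4.56,1.71,9.23,3.83
Primary somatosensory cortex GM,1.57,0.53,7.22,2.33,7.91,2.69,5.11,1.63,9.37,3.06
Pallidum,2.11,0.94,8.88,3.75,8.18,4.30,4.31,2.03,8.43,4.06
Hippocampus,2.18,1.01,7.37,3.35,6.83,3.67,5.78,2.74,7.12,3.73
Corpus callosum,2.07,0.88,5.93,2.62,6.54,3.46,5.25,2.31,9.50,4.28
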