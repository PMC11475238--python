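# Transcription of the published region fitting-quality table: retained ROIs
# grouped by the joint-CRLB classification (good: > 80% of voxels with
# NAA/tCr/tCho/mIns CRLBs < 40%; acceptable: 66-79%), estimated GM/WM
# content [%], mean ROI size [cm^3], and per-metabolite percentages of
# voxels passing the individual CRLB criterion (< 20% for NAA, tCr, tCho,
# mIns; < 40% for the rest).  Mean rows are recomputed, not stored.
roi,group,gm_pct,wm_pct,size_cm3,tCho,tCr,GABA,Glu,Gln,Gly,GSH,mIns,NAA,NAAG,Ser,Tau
Subcortical WM (left),good,35,63,101.4,85,81,47,83,50,33,46,78,84,59,61,52
Subcortical WM (right),good,35,62,101.0,87,84,50,85,52,34,50,82,85,62,62,57
Subcortical WM (bilateral),good,35,63,202.4,86,82,48,84,51,33,48,80,85,61,61,54
Motor subcortex WM,good,31,68,18.4,98,97,74,97,50,54,54,97,98,90,78,78
Motor cortex GM,good,63,27,18.7,86,83,62,86,55,36,32,81,87,70,67,70
Motor cortex/subcortex GM+WM,good,47,47,37.1,92,90,68,92,53,45,43,89,92,80,72,74
Parietal subcortex WM,good,35,64,47.6,98,97,64,96,60,54,58,96,98,84,78,77
Parietal cortex GM,good,63,27,66.0,91,89,62,91,66,45,42,87,92,72,71,76
Parietal cortex/subcortex GM+WM,good,50,44,103.6,94,93,63,93,63,49,49,91,95,77,74,77
Cingulate subcortex WM,good,31,69,13.8,91,87,53,88,37,26,64,84,91,64,61,40
Cingulate cortex GM,good,77,23,11.0,91,89,66,92,60,29,52,85,91,68,68,62
Cingulate cortex/subcortex GM+WM,good,51,49,24.9,91,88,59,90,47,27,58,84,91,66,64,50
Visual subcortex WM,good,33,60,13.6,90,82,29,84,39,33,40,74,89,49,71,56
Primary somatosensory subcortex WM,good,39,57,7.2,95,93,64,95,61,41,40,93,95,80,74,72
Primary somatosensory cortex/subcortex GM+WM,good,49,41,16.8,87,84,57,87,57,36,32,83,88,69,66,67
Thalamus,good,42,58,7.4,90,84,49,84,37,14,51,75,87,58,53,27
Putamen,good,55,45,5.1,89,86,39,90,67,11,53,72,87,46,54,32
Non-lobe WM,good,10,90,31.9,94,91,45,86,34,31,73,86,93,68,61,36
Cortical GM (left),acceptable,65,26,124.3,69,63,40,69,48,23,30,59,69,44,50,47
Cortical GM (right),acceptable,61,25,123.9,78,74,46,77,55,28,36,71,77,52,55,57
Cortical GM (bilateral),acceptable,63,25,248.2,73,69,43,73,52,25,33,65,73,48,52,52
Cortical GM + subcortical WM (left),acceptable,51,43,225.7,76,71,43,75,49,27,37,68,76,51,55,49
Cortical GM + subcortical WM (right),acceptable,49,43,224.9,82,78,48,81,54,30,42,76,81,57,58,57
Cortical GM + subcortical WM (bilateral),acceptable,50,43,443.8,79,75,46,78,51,29,40,72,78,54,56,53
Subcortical GM (left),acceptable,51,48,14.8,83,78,35,78,43,11,52,65,78,44,42,25
Subcortical GM (right),acceptable,50,50,14.4,77,68,32,68,40,9,45,57,69,32,39,19
Subcortical GM (bilateral),acceptable,51,49,29.3,80,73,33,72,41,10,49,61,74,38,40,22
Auditory subcortex WM,acceptable,43,53,7.0,85,79,39,81,62,19,41,75,79,42,55,42
Auditory cortex GM,acceptable,62,24,12.2,73,67,35,70,55,15,31,60,68,33,45,41
Auditory cortex/subcortex GM+WM,acceptable,54,36,19.2,77,71,36,74,58,16,35,66,72,36,49,41
Occipital subcortex WM,acceptable,34,61,22.4,86,79,30,80,40,30,39,73,84,45,64,51
Occipital cortex GM,acceptable,59,28,29.5,75,66,30,73,41,22,28,60,74,40,56,49
Occipital cortex/subcortex GM+WM,acceptable,48,43,51.9,80,71,30,76,41,26,33,65,78,42,59,50
Temporal subcortex WM,acceptable,38,59,33.8,72,67,33,70,50,19,39,64,69,43,47,35
Temporal cortex/subcortex GM+WM,acceptable,52,41,77.0,66,60,32,64,49,17,33,56,62,38,44,35
Frontal subcortex WM,acceptable,34,64,80.8,82,80,50,83,51,28,46,77,82,57,55,50
Frontal cortex GM,acceptable,62,23,96.4,66,62,41,68,48,17,31,59,67,41,43,44
Frontal cortex/subcortex GM+WM,acceptable,49,43,177.2,73,70,45,74,50,22,38,67,74,48,48,47
Visual cortex GM,acceptable,55,28,17.1,76,65,26,76,39,22,27,58,79,42,61,49
Visual cortex/subcortex GM+WM,acceptable,45,43,30.7,82,73,27,80,39,27,33,65,84,45,65,52
Primary somatosensory cortex GM,acceptable,57,28,9.6,80,77,52,81,55,32,26,75,82,61,60,63
Pallidum,acceptable,13,87,1.9,81,79,37,75,43,4,53,55,76,32,35,13
Hippocampus,acceptable,72,26,4.1,81,69,23,65,37,12,51,56,66,27,28,23
Corpus callosum,acceptable,29,71,1.8,83,73,41,77,25,17,58,68,82,49,48,19
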