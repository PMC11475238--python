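# Transcription: segmented regions below the joint-CRLB quality threshold,
# excluded from the regional analysis.
roi
Brain stem
Cerebellum (left)
Cerebellum (right)
Cerebellum (bilateral)
Cerebral WM (left)
Cerebral WM (right)
Cerebral WM (bilateral)
Amygdala
Nucleus accumbens
Temporal cortex (GM)
Ventral diencephalon
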